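"""Synthetic structures with exactly known ground-truth geometry.

Every analysis stage in this package is testable without downloading any
deposited model, because the generators here emit structures whose
geometric answers are prescribed:

* :func:`build_bilin` — a CYC-named open-chain tetrapyrrole with the four
  pyrrole rings A-D, bridge carbons CHB/CHC/CHD, keto oxygens OA/OD and
  propionate arms on rings B/C, constructed with exact inter-ring plane
  angles (theta_AB, theta_BC, theta_CD) and an exact methine-bridge
  stereodescriptor (e.g. "ZZZ,ssa").
* :func:`build_cylinder_pair` — two stacks of pseudo-(alpha-beta)_3 rings
  whose best-fit axes subtend exactly the prescribed (folded) twist, in
  the antiparallel arrangement of the FR-APC bicylinder, related by an
  exact C2 rotation, with optional ApcC / ApcE2-REP decoy chains that the
  centroid calculation must exclude and optional per-subunit CYC ligands
  (3 alpha-site + 3 beta-site per ring).
* :func:`build_c2_dimer` — a chain plus its copy rotated by a prescribed
  angle about a prescribed axis.
* :func:`build_pocket` — a bilin with partner residues placed so that a
  named partner atom sits at an exact distance from a named bilin atom
  (or a partner aromatic ring stacks plane-parallel on a named bilin
  ring), along a clash-free direction.

Geometry is the only design goal: bond lengths and angles are plausible
but not energy-minimized, and pseudo-subunits are backbone-only.  Noise,
where requested, is iid isotropic Gaussian per atom under a mandatory
seed; the same spec and seed always produce byte-identical structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from string import ascii_uppercase, ascii_lowercase, digits
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from ._geom import dihedral_deg, rotate_about_line, rotation_about_axis, unit
from .bilin_geometry import (
    BilinChromophore,
    classify_conformer,
    interplane_angle,
)
from .errors import InfeasibleFixtureError
from .model import AtomSite, ChainAnnotation, ResidueRecord, StructureModel

__all__ = [
    "SyntheticBilinSpec",
    "SyntheticAssemblySpec",
    "PartnerSpec",
    "build_bilin",
    "build_cylinder_pair",
    "build_c2_dimer",
    "build_pocket",
    "bilin_model",
]

_RING_IDS = ("A", "B", "C", "D")
_PENTAGON_RADIUS = 1.17  # gives ~1.38 A ring bonds
_BOND = 1.38


# ---------------------------------------------------------------------------
# Bilin generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticBilinSpec:
    """Prescribed geometry for one synthetic bilin."""

    theta_AB: float = 0.0
    theta_BC: float = 0.0
    theta_CD: float = 0.0
    conformer: str = "ZZZ,ssa"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_AB", "theta_BC", "theta_CD"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name}={v} outside [0, 90]")
        cfg, conf = _parse_conformer(self.conformer)
        del cfg, conf  # validation only


def _parse_conformer(label: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    try:
        cfg_part, conf_part = label.split(",")
    except ValueError as exc:
        raise ValueError(f"conformer label {label!r} must look like 'ZZZ,ssa'") from exc
    cfg = tuple(cfg_part)
    conf = tuple(conf_part)
    if len(cfg) != 3 or any(c not in "ZE" for c in cfg):
        raise ValueError(f"bad configuration part {cfg_part!r}")
    if len(conf) != 3 or any(c not in "sa" for c in conf):
        raise ValueError(f"bad conformation part {conf_part!r}")
    return cfg, conf


def _pentagon_local() -> dict[str, np.ndarray]:
    """Local pyrrole template in the z=0 plane: N, C1..C4 clockwise from the top."""
    coords = {}
    names = ["N", "C1", "C2", "C3", "C4"]
    for k, name in enumerate(names):
        ang = math.radians(90.0 - 72.0 * k)
        coords[name] = np.array(
            [_PENTAGON_RADIUS * math.cos(ang), _PENTAGON_RADIUS * math.sin(ang), 0.0]
        )
    return coords


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    """Rotate an in-plane (z=0) vector about +z."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


class _BilinBuilder:
    """Assembles the planar baseline, then sets torsions and ring tilts."""

    def __init__(self) -> None:
        self.coords: dict[str, np.ndarray] = {}
        self.bonds: list[tuple[str, str]] = []

    def _place_ring(self, ring: str, center: np.ndarray, phi_deg: float) -> None:
        template = _pentagon_local()
        for local_name, local in template.items():
            name = (
                f"N{ring}" if local_name == "N" else f"{local_name[0]}{local_name[1]}{ring}"
            )
            self.coords[name] = center + _rot2(local, phi_deg)
        ring_names = [f"N{ring}", f"C1{ring}", f"C2{ring}", f"C3{ring}", f"C4{ring}"]
        for a, b in zip(ring_names, ring_names[1:] + ring_names[:1]):
            self.bonds.append((a, b))

    def _outward(self, ring: str, atom: str) -> np.ndarray:
        center = np.mean(
            [self.coords[f"{p}{ring}"] for p in ("N", "C1", "C2", "C3", "C4")], axis=0
        )
        return unit(self.coords[atom] - center)

    def assemble_baseline(self) -> None:
        # ring B is the fixed reference at the origin
        self._place_ring("B", np.zeros(3), 0.0)

        # A side: C1B -> CHB -> C4A
        out_c1b = self._outward("B", "C1B")
        chb = self.coords["C1B"] + _BOND * out_c1b
        self.coords["CHB"] = chb
        dir_a = _rot2(out_c1b, 60.0)  # ~120 deg bridge angle, avoids collinearity
        c4a = chb + _BOND * dir_a
        # orient ring A so that its C4 exocyclic direction points back at CHB
        phi_a = math.degrees(math.atan2(-dir_a[1], -dir_a[0])) - (90.0 - 72.0 * 4)
        center_a = c4a - _PENTAGON_RADIUS * (-dir_a)
        self._place_ring("A", center_a, phi_a)
        self.coords["C4A"] = c4a  # exact attachment
        self.bonds += [("C1B", "CHB"), ("CHB", "C4A")]

        # C side: C4B -> CHC -> C1C
        out_c4b = self._outward("B", "C4B")
        chc = self.coords["C4B"] + _BOND * out_c4b
        self.coords["CHC"] = chc
        dir_c = _rot2(out_c4b, -60.0)
        c1c = chc + _BOND * dir_c
        phi_c = math.degrees(math.atan2(-dir_c[1], -dir_c[0])) - (90.0 - 72.0)
        center_c = c1c - _PENTAGON_RADIUS * (-dir_c)
        self._place_ring("C", center_c, phi_c)
        self.coords["C1C"] = c1c
        self.bonds += [("C4B", "CHC"), ("CHC", "C1C")]

        # D side: C4C -> CHD -> C1D
        out_c4c = self._outward("C", "C4C")
        chd = self.coords["C4C"] + _BOND * out_c4c
        self.coords["CHD"] = chd
        dir_d = _rot2(out_c4c, 60.0)
        c1d = chd + _BOND * dir_d
        phi_d = math.degrees(math.atan2(-dir_d[1], -dir_d[0])) - (90.0 - 72.0)
        center_d = c1d - _PENTAGON_RADIUS * (-dir_d)
        self._place_ring("D", center_d, phi_d)
        self.coords["C1D"] = c1d
        self.bonds += [("C4C", "CHD"), ("CHD", "C1D")]

        # keto oxygens on the free ends of rings A and D
        self.coords["OA"] = self.coords["C1A"] + 1.23 * self._outward("A", "C1A")
        self.coords["OD"] = self.coords["C4D"] + 1.23 * self._outward("D", "C4D")
        self.bonds += [("C1A", "OA"), ("C4D", "OD")]

        # propionate arms on rings B and C
        for ring in ("B", "C"):
            u = self._outward(ring, f"C2{ring}")
            base = self.coords[f"C2{ring}"]
            ca = base + 1.50 * u
            cb = ca + 1.50 * _rot2(u, 30.0)
            cg = cb + 1.50 * _rot2(u, -30.0)
            o1 = cg + 1.25 * _rot2(u, 30.0)
            o2 = cg + 1.25 * _rot2(u, -80.0)
            self.coords[f"CA{ring}"] = ca
            self.coords[f"CB{ring}"] = cb
            self.coords[f"CG{ring}"] = cg
            self.coords[f"O1{ring}"] = o1
            self.coords[f"O2{ring}"] = o2
            self.bonds += [
                (f"C2{ring}", f"CA{ring}"),
                (f"CA{ring}", f"CB{ring}"),
                (f"CB{ring}", f"CG{ring}"),
                (f"CG{ring}", f"O1{ring}"),
                (f"CG{ring}", f"O2{ring}"),
            ]

    # -- fragment machinery ------------------------------------------------
    def _component(self, start: str, blocked_edge: tuple[str, str]) -> set[str]:
        adjacency: dict[str, set[str]] = {}
        for a, b in self.bonds:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt in adjacency.get(node, ()):
                if {node, nxt} == set(blocked_edge):
                    continue
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def _rotate_fragment(
        self, fragment: Iterable[str], origin: str, axis_to: str, angle_deg: float
    ) -> None:
        names = list(fragment)
        pts = np.array([self.coords[n] for n in names])
        moved = rotate_about_line(
            pts,
            self.coords[origin],
            self.coords[axis_to] - self.coords[origin],
            angle_deg,
        )
        for name, p in zip(names, moved):
            self.coords[name] = p

    def _torsion(self, quad: Sequence[str]) -> float:
        return dihedral_deg(*(self.coords[n] for n in quad))

    def set_torsion(self, quad: Sequence[str], target: float, move_from: str) -> None:
        """Rotate the fragment on the ``move_from`` side of the central bond
        so the dihedral over ``quad`` equals ``target`` (degrees)."""
        a, b, c, d = quad
        fragment = self._component(move_from, (b, c))
        current = self._torsion(quad)
        delta = (target - current + 180.0) % 360.0 - 180.0
        if abs(delta) < 1e-12:
            return
        self._rotate_fragment(fragment, b, c, delta)
        # the rotation sign depends on which side moved; correct if needed
        err = (self._torsion(quad) - target + 180.0) % 360.0 - 180.0
        if abs(err) > 1e-9:
            self._rotate_fragment(fragment, b, c, -2.0 * delta)
        err = (self._torsion(quad) - target + 180.0) % 360.0 - 180.0
        if abs(err) > 1e-9:
            raise InfeasibleFixtureError(f"cannot set torsion {quad} to {target}")

    def tilt_fragment(self, origin: str, axis_to: str, move_from: str, angle_deg: float) -> None:
        fragment = self._component(move_from, (origin, axis_to))
        self._rotate_fragment(fragment, origin, axis_to, angle_deg)


def _element_of(name: str) -> str:
    return name[0]


def build_bilin(spec: SyntheticBilinSpec) -> tuple[ResidueRecord, dict]:
    """A synthetic CYC residue realizing ``spec`` exactly, plus its ground truth.

    The returned ground truth maps the prescribed angles and conformer
    label; at zero noise the construction is verified against the
    package's own analyzers and raises :class:`InfeasibleFixtureError` if
    the requested conformer cannot coexist with the requested angles.
    """
    cfg, conf = _parse_conformer(spec.conformer)
    builder = _BilinBuilder()
    builder.assemble_baseline()

    # methine-bridge torsions: configuration about C4X-CH, conformation about CH-C1Y
    bridge_quads = [
        (("NA", "C4A", "CHB", "C1B"), ("C4A", "CHB", "C1B", "NB"), "NA", "NA"),
        (("NB", "C4B", "CHC", "C1C"), ("C4B", "CHC", "C1C", "NC"), "C1C", "NC"),
        (("NC", "C4C", "CHD", "C1D"), ("C4C", "CHD", "C1D", "ND"), "C1D", "ND"),
    ]
    for k, (cfg_quad, conf_quad, cfg_side, conf_side) in enumerate(bridge_quads):
        builder.set_torsion(cfg_quad, 0.0 if cfg[k] == "Z" else 180.0, cfg_side)
        builder.set_torsion(conf_quad, 0.0 if conf[k] == "s" else 180.0, conf_side)

    # ring tilts about the bridge bonds: exact inter-plane angles
    if spec.theta_AB:
        builder.tilt_fragment("CHB", "C4A", "NA", spec.theta_AB)
    if spec.theta_BC:
        builder.tilt_fragment("C4B", "CHC", "C1C", spec.theta_BC)
    if spec.theta_CD:
        builder.tilt_fragment("CHD", "C1D", "ND", spec.theta_CD)

    atoms = [
        AtomSite(atom_name=name, element=_element_of(name), coords=coords)
        for name, coords in builder.coords.items()
    ]
    residue = ResidueRecord(
        comp_id="CYC", seq_id=1, chain_id="X", atoms=atoms, is_polymer=False
    )

    # verify the noise-free construction against the package's own analyzers
    bilin = BilinChromophore.from_residue(residue)
    realized = (
        interplane_angle(bilin.plane_normals["A"], bilin.plane_normals["B"]),
        interplane_angle(bilin.plane_normals["B"], bilin.plane_normals["C"]),
        interplane_angle(bilin.plane_normals["C"], bilin.plane_normals["D"]),
    )
    wanted = (spec.theta_AB, spec.theta_BC, spec.theta_CD)
    if max(abs(r - w) for r, w in zip(realized, wanted)) > 1e-6:
        raise InfeasibleFixtureError(
            f"angle construction failed: wanted {wanted}, realized {realized}"
        )
    label = classify_conformer(bilin).label
    if label != spec.conformer:
        raise InfeasibleFixtureError(
            f"conformer {spec.conformer!r} unrealizable with angles {wanted} "
            f"(construction classifies as {label!r})"
        )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = [
            atom.moved_to(atom.coords + rng.normal(0.0, spec.noise_sigma, 3))
            for atom in residue.atoms
        ]
        residue = ResidueRecord(
            comp_id="CYC", seq_id=1, chain_id="X", atoms=noisy, is_polymer=False
        )

    ground_truth = {
        "theta_AB": spec.theta_AB,
        "theta_BC": spec.theta_BC,
        "theta_CD": spec.theta_CD,
        "conformer": spec.conformer,
        "noise_sigma": spec.noise_sigma,
    }
    return residue, ground_truth


def bilin_model(
    residue: ResidueRecord, subunit_role: str = "other", entry_id: str = "synthetic-bilin"
) -> StructureModel:
    """Wrap a single bilin residue as an annotated one-chain model."""
    ann = ChainAnnotation(chain_id=residue.chain_id, subunit_role=subunit_role)
    return StructureModel(entry_id=entry_id, chains=[(ann, [residue])])


# ---------------------------------------------------------------------------
# Cylinder pair / C2 dimer generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticAssemblySpec:
    """Prescribed geometry for a bicylindrical pseudo-APC assembly."""

    n_rings: int = 4
    ring_spacing: float = 30.0
    twist_deg: float = 30.0
    antiparallel: bool = True
    c2_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    separation: float = 55.0
    ring_radius: float = 12.0
    residues_per_chain: int = 8
    decoys: tuple[str, ...] = ()
    with_bilins: bool = False
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ring_spacing <= 0:
            raise ValueError("ring_spacing must be positive")
        if self.n_rings < 2:
            raise ValueError("a cylinder needs at least 2 rings")
        if not 0.0 <= self.twist_deg <= 90.0:
            raise ValueError("twist_deg must be in [0, 90]")
        for decoy in self.decoys:
            if decoy not in ("ApcC", "ApcE2-REP"):
                raise ValueError(f"unknown decoy kind {decoy!r}")


_ALPHA_ROLES = ("ApcD2", "ApcD3", "ApcD5")
_BETA_ROLE = "ApcB2"


class _ChainIdPool:
    def __init__(self) -> None:
        single = list(ascii_uppercase + ascii_lowercase + digits)
        # two-character ids overflow the PDB column but are valid in mmCIF
        self._pool = single + [a + b for a in ascii_uppercase for b in single]
        self._next = 0

    def take(self) -> str:
        if self._next >= len(self._pool):
            raise InfeasibleFixtureError("fixture needs too many chains")
        cid = self._pool[self._next]
        self._next += 1
        return cid


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane normal to ``axis``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(axis, helper))
    e2 = np.cross(axis, e1)
    return e1, e2


def _backbone_residue(
    chain_id: str, seq_id: int, center: np.ndarray, e1: np.ndarray, e2: np.ndarray,
    radius: float, theta_deg: float, delta_deg: float = 3.0,
) -> ResidueRecord:
    def on_circle(r: float, ang_deg: float) -> np.ndarray:
        ang = math.radians(ang_deg)
        return center + r * (math.cos(ang) * e1 + math.sin(ang) * e2)

    atoms = [
        AtomSite("N", "N", on_circle(radius, theta_deg - delta_deg)),
        AtomSite("CA", "C", on_circle(radius, theta_deg)),
        AtomSite("C", "C", on_circle(radius, theta_deg + delta_deg)),
        AtomSite("O", "O", on_circle(radius + 1.2, theta_deg + delta_deg)),
    ]
    return ResidueRecord(comp_id="ALA", seq_id=seq_id, chain_id=chain_id, atoms=atoms)


def _transform_residue(res: ResidueRecord, R: np.ndarray, t: np.ndarray,
                       chain_id: str) -> ResidueRecord:
    moved = res.transformed(R, t)
    return ResidueRecord(
        comp_id=moved.comp_id, seq_id=moved.seq_id, chain_id=chain_id,
        atoms=moved.atoms, is_polymer=moved.is_polymer,
    )


def build_cylinder_pair(spec: SyntheticAssemblySpec) -> tuple[StructureModel, dict]:
    """A pseudo-APC bicylinder with exact twist, C2 symmetry and decoys.

    Cylinder 1 is built explicitly; cylinder 2 is its exact image under a
    180-degree rotation about ``spec.c2_axis``.  The cylinder axes are
    tilted off the C2 axis so that the folded angle between them is
    exactly ``spec.twist_deg`` — in the antiparallel arrangement (the
    FR-APC case) the raw inter-axis angle is 180 - twist.

    Returns the annotated model plus a ground-truth dict with the ring
    centers, axes, folded twist, C2 axis and the chain pairing between the
    two halves.
    """
    k = unit(np.asarray(spec.c2_axis, dtype=float), "c2 axis")
    raw_angle = 180.0 - spec.twist_deg if spec.antiparallel else spec.twist_deg
    beta = math.radians(raw_angle / 2.0)
    e1, e2 = _orthonormal_frame(k)
    # cylinder-1 axis: tilted off the C2 axis by half the raw angle
    u1 = math.sin(beta) * e1 + math.cos(beta) * k
    c2_rotation = rotation_about_axis(k, 180.0)
    u2 = c2_rotation @ u1

    half_span = 0.5 * (spec.n_rings - 1) * spec.ring_spacing
    center1 = 0.5 * spec.separation * e2
    base1 = center1 - half_span * u1
    ring_centers_1 = [base1 + i * spec.ring_spacing * u1 for i in range(spec.n_rings)]

    pool = _ChainIdPool()
    chains: list[tuple[ChainAnnotation, list[ResidueRecord]]] = []
    half_a_ids: list[str] = []
    rng = np.random.default_rng(spec.seed)

    f1, f2 = _orthonormal_frame(u1)
    cylinder1: list[tuple[ChainAnnotation, list[ResidueRecord]]] = []
    n_res = spec.residues_per_chain

    bilin_template: Optional[ResidueRecord] = None
    if spec.with_bilins:
        bilin_template, _ = build_bilin(SyntheticBilinSpec())

    for ring_i, center in enumerate(ring_centers_1, start=1):
        ring_index = ring_i if ring_i <= 4 else None  # annotation supports 4 rings
        for sub in range(6):
            cid = pool.take()
            role = _ALPHA_ROLES[sub // 2] if sub % 2 == 0 else _BETA_ROLE
            residues = []
            arc0 = sub * 60.0
            for r in range(n_res):
                theta = arc0 + (r + 0.5) * 60.0 / n_res
                residues.append(
                    _backbone_residue(
                        cid, r + 1, center, f1, f2, spec.ring_radius, theta
                    )
                )
            if spec.with_bilins and bilin_template is not None:
                mid = math.radians(arc0 + 30.0)
                site = center + (spec.ring_radius - 4.0) * (
                    math.cos(mid) * f1 + math.sin(mid) * f2
                )
                Rb = rotation_about_axis(u1, arc0 + 30.0)
                placed = _transform_residue(bilin_template, Rb, site, cid)
                placed = ResidueRecord(
                    comp_id="CYC", seq_id=201, chain_id=cid,
                    atoms=placed.atoms, is_polymer=False,
                )
                residues.append(placed)
            ann = ChainAnnotation(
                chain_id=cid, subunit_role=role, cylinder_index=1, ring_index=ring_index
            )
            cylinder1.append((ann, residues))
            half_a_ids.append(cid)

        if "ApcC" in spec.decoys:
            cid = pool.take()
            decoy_center = center + 6.0 * u1 + 3.0 * f1
            residues = [
                _backbone_residue(cid, r + 1, decoy_center, f1, f2, 2.5, r * 70.0)
                for r in range(3)
            ]
            ann = ChainAnnotation(
                chain_id=cid, subunit_role="ApcC", cylinder_index=1, ring_index=ring_index
            )
            cylinder1.append((ann, residues))
            half_a_ids.append(cid)

        if "ApcE2-REP" in spec.decoys:
            cid = pool.take()
            decoy_center = center - 5.0 * u1 - 4.0 * f2
            residues = [
                _backbone_residue(cid, 100 + r, decoy_center, f1, f2, 3.0, r * 50.0)
                for r in range(4)
            ]
            ann = ChainAnnotation(
                chain_id=cid,
                subunit_role="ApcE2",
                cylinder_index=1,
                ring_index=ring_index,
                rep_domain_ranges=[(100, 100 + 3)],
            )
            cylinder1.append((ann, residues))
            half_a_ids.append(cid)

    chains.extend(cylinder1)

    # cylinder 2: exact C2 image of cylinder 1
    pairing: dict[str, str] = {}
    for ann, residues in cylinder1:
        cid = pool.take()
        pairing[ann.chain_id] = cid
        moved = [
            _transform_residue(res, c2_rotation, np.zeros(3), cid) for res in residues
        ]
        ann2 = ChainAnnotation(
            chain_id=cid,
            subunit_role=ann.subunit_role,
            cylinder_index=2,
            ring_index=ann.ring_index,
            rep_domain_ranges=list(ann.rep_domain_ranges),
        )
        chains.append((ann2, moved))

    model = StructureModel(entry_id="synthetic-bicylinder", chains=chains)

    if spec.noise_sigma > 0:
        noisy_chains = []
        for ann, residues in model.chains:
            noisy_res = []
            for res in residues:
                atoms = [
                    a.moved_to(a.coords + rng.normal(0.0, spec.noise_sigma, 3))
                    for a in res.atoms
                ]
                noisy_res.append(
                    ResidueRecord(
                        comp_id=res.comp_id, seq_id=res.seq_id, chain_id=res.chain_id,
                        atoms=atoms, is_polymer=res.is_polymer,
                    )
                )
            noisy_chains.append((ann, noisy_res))
        model = StructureModel(entry_id=model.entry_id, chains=noisy_chains)

    ground_truth = {
        "twist_deg": spec.twist_deg,
        "raw_axis_angle_deg": raw_angle,
        "axis_1": u1,
        "axis_2": u2,
        "ring_centers_1": np.array(ring_centers_1),
        "ring_centers_2": np.array([c2_rotation @ c for c in ring_centers_1]),
        "c2_axis": k,
        "c2_point": np.zeros(3),
        "half_a": half_a_ids,
        "half_b": [pairing[c] for c in half_a_ids],
        "pairing": pairing,
    }
    return model, ground_truth


def build_c2_dimer(
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    point: Sequence[float] = (0.0, 0.0, 0.0),
    rotation_angle: float = 180.0,
    n_residues: int = 40,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, dict]:
    """A CA-trace chain plus its copy rotated about an arbitrary axis.

    With the default 180-degree rotation this is an exact C2 dimer; other
    angles deliberately produce non-two-fold pairs for negative tests.
    """
    rng = np.random.default_rng(seed)
    axis_u = unit(np.asarray(axis, dtype=float), "c2 axis")
    point = np.asarray(point, dtype=float)

    steps = rng.normal(size=(n_residues, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.cumsum(steps, axis=0) + np.array([15.0, 5.0, 0.0])

    R = rotation_about_axis(axis_u, rotation_angle)
    ca_b = (ca - point) @ R.T + point
    if noise_sigma > 0:
        ca = ca + rng.normal(0.0, noise_sigma, ca.shape)
        ca_b = ca_b + rng.normal(0.0, noise_sigma, ca_b.shape)

    def chain(cid: str, coords: np.ndarray) -> tuple[ChainAnnotation, list[ResidueRecord]]:
        residues = [
            ResidueRecord(
                comp_id="GLY", seq_id=i + 1, chain_id=cid,
                atoms=[AtomSite("CA", "C", c)],
            )
            for i, c in enumerate(coords)
        ]
        return ChainAnnotation(chain_id=cid), residues

    model = StructureModel(
        entry_id="synthetic-c2-dimer", chains=[chain("A", ca), chain("B", ca_b)]
    )
    ground_truth = {
        "axis": axis_u,
        "point": point,
        "rotation_angle": rotation_angle,
        "pairing": {"A": "B"},
    }
    return model, ground_truth


# ---------------------------------------------------------------------------
# Pocket generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartnerSpec:
    """One partner residue to place around a bilin.

    For ``contact_type='pi_stack'`` give ``bilin_ring`` (A-D) and the
    partner ring is stacked plane-parallel at ``distance`` along the bilin
    ring normal; otherwise ``bilin_atom`` and ``partner_atom`` name the
    exact contact pair.
    """

    res_name: str
    contact_type: str  # hbond | salt_bridge | pi_stack | steric
    distance: float
    partner_atom: str = ""
    bilin_atom: str = ""
    bilin_ring: str = ""
    chain_id: str = "P"
    seq_id: int = 1


def _hexagon(center: np.ndarray, first_angle: float, names: Sequence[str],
             radius: float = 1.39) -> dict[str, np.ndarray]:
    out = {}
    for k, name in enumerate(names):
        ang = math.radians(first_angle - 60.0 * k)
        out[name] = center + radius * np.array([math.cos(ang), math.sin(ang), 0.0])
    return out


def _pentagon_at(center: np.ndarray, first_angle: float, names: Sequence[str],
                 radius: float = 1.17) -> dict[str, np.ndarray]:
    out = {}
    for k, name in enumerate(names):
        ang = math.radians(first_angle - 72.0 * k)
        out[name] = center + radius * np.array([math.cos(ang), math.sin(ang), 0.0])
    return out


def _residue_templates() -> dict[str, dict[str, np.ndarray]]:
    """Idealized local coordinates per supported residue (z=0 backbone at top)."""
    backbone = {
        "N": np.array([-1.2, 0.8, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.3, 0.6, 0.0]),
        "O": np.array([1.4, 1.8, 0.0]),
    }

    def with_backbone(side: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {**backbone, **side}

    templates: dict[str, dict[str, np.ndarray]] = {}
    templates["ALA"] = with_backbone({"CB": np.array([-0.5, -1.4, 0.3])})
    templates["SER"] = with_backbone(
        {"CB": np.array([-0.5, -1.4, 0.3]), "OG": np.array([-0.1, -2.7, 0.2])}
    )
    templates["THR"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "OG1": np.array([-0.05, -2.7, 0.2]),
            "CG2": np.array([-2.0, -1.5, 0.3]),
        }
    )
    templates["CYS"] = with_backbone(
        {"CB": np.array([-0.5, -1.4, 0.3]), "SG": np.array([0.1, -3.0, 0.2])}
    )
    templates["MET"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "CG": np.array([-0.1, -2.8, 0.3]),
            "SD": np.array([-0.7, -4.3, 0.2]),
            "CE": np.array([0.2, -5.6, 0.2]),
        }
    )
    templates["ASN"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "CG": np.array([-0.1, -2.8, 0.2]),
            "OD1": np.array([1.05, -3.2, 0.2]),
            "ND2": np.array([-1.05, -3.65, 0.1]),
        }
    )
    templates["ASP"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "CG": np.array([-0.1, -2.8, 0.2]),
            "OD1": np.array([1.05, -3.2, 0.2]),
            "OD2": np.array([-1.05, -3.65, 0.1]),
        }
    )
    templates["GLN"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "CG": np.array([-0.1, -2.8, 0.3]),
            "CD": np.array([-0.7, -4.1, 0.2]),
            "OE1": np.array([-1.9, -4.3, 0.1]),
            "NE2": np.array([0.1, -5.1, 0.1]),
        }
    )
    templates["GLU"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "CG": np.array([-0.1, -2.8, 0.3]),
            "CD": np.array([-0.7, -4.1, 0.2]),
            "OE1": np.array([-1.9, -4.3, 0.1]),
            "OE2": np.array([0.1, -5.1, 0.1]),
        }
    )
    templates["LYS"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "CG": np.array([-0.1, -2.8, 0.3]),
            "CD": np.array([-0.7, -4.1, 0.2]),
            "CE": np.array([-0.2, -5.5, 0.2]),
            "NZ": np.array([-0.9, -6.7, 0.1]),
        }
    )
    templates["ARG"] = with_backbone(
        {
            "CB": np.array([-0.5, -1.4, 0.3]),
            "CG": np.array([-0.1, -2.8, 0.3]),
            "CD": np.array([-0.6, -4.1, 0.2]),
            "NE": np.array([-0.1, -5.4, 0.2]),
            "CZ": np.array([-0.7, -6.6, 0.1]),
            "NH1": np.array([-2.0, -6.7, 0.1]),
            "NH2": np.array([0.05, -7.65, 0.0]),
        }
    )

    hex_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    hex_center = np.array([-0.3, -3.3, 0.0])
    phe_ring = _hexagon(hex_center, 90.0, hex_names)
    templates["PHE"] = with_backbone({"CB": np.array([-0.5, -1.4, 0.0]), **phe_ring})
    tyr_ring = dict(phe_ring)
    oh_dir = unit(tyr_ring["CZ"] - hex_center)
    tyr_ring["OH"] = tyr_ring["CZ"] + 1.36 * oh_dir
    templates["TYR"] = with_backbone({"CB": np.array([-0.5, -1.4, 0.0]), **tyr_ring})

    his_ring = _pentagon_at(np.array([-0.2, -3.0, 0.0]), 90.0,
                            ("CG", "ND1", "CE1", "NE2", "CD2"))
    templates["HIS"] = with_backbone({"CB": np.array([-0.5, -1.4, 0.0]), **his_ring})

    # TRP: fused pentagon + hexagon sharing the CD2-CE2 edge
    p5c = np.array([-0.2, -3.0, 0.0])
    trp5 = _pentagon_at(p5c, 90.0, ("CG", "CD1", "NE1", "CE2", "CD2"))
    mid = 0.5 * (trp5["CE2"] + trp5["CD2"])
    out_dir = unit(mid - p5c)
    hx_center = mid + 1.204 * out_dir  # hexagon apothem for 1.39 A bonds
    ang_ce2 = math.degrees(math.atan2(*(trp5["CE2"] - hx_center)[[1, 0]]))
    ang_cd2 = math.degrees(math.atan2(*(trp5["CD2"] - hx_center)[[1, 0]]))
    step = (ang_cd2 - ang_ce2 + 180.0) % 360.0 - 180.0
    sign = 1.0 if step > 0 else -1.0
    trp6 = {}
    for k, name in enumerate(("CZ2", "CH2", "CZ3", "CE3")):
        ang = math.radians(ang_ce2 - sign * 60.0 * (k + 1))
        trp6[name] = hx_center + 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
    templates["TRP"] = with_backbone(
        {"CB": np.array([-0.5, -1.4, 0.0]), **trp5, **trp6}
    )
    return templates


_TEMPLATES = _residue_templates()

_TEMPLATE_RINGS = {
    "PHE": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "TYR": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "HIS": ("CG", "ND1", "CE1", "NE2", "CD2"),
    "TRP": ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
}

_CLEARANCE = 2.45  # A; minimum approach of any non-contact atom pair


def _fibonacci_directions(n: int = 64) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi * k), r * np.sin(phi * k), z], axis=1)


def _place_template(
    template: dict[str, np.ndarray],
    anchor_atom: str,
    target_point: np.ndarray,
    direction: np.ndarray,
    secondary: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> dict[str, np.ndarray]:
    """Rigidly place a template so ``anchor_atom`` lands on ``target_point``
    with the CA->anchor direction along ``direction`` (the residue body
    trails away opposite the contact).  ``secondary`` optionally adds a
    (local_vector, world_vector) pair to pin the orientation (used to make
    aromatic ring planes parallel to a bilin ring)."""
    local_anchor = template[anchor_atom]
    v_local = unit(local_anchor - template["CA"])
    vecs_local = [v_local]
    vecs_world = [unit(direction)]
    if secondary is not None:
        vecs_local.append(unit(secondary[0]))
        vecs_world.append(unit(secondary[1]))
    rot, _ = Rotation.align_vectors(np.array(vecs_world), np.array(vecs_local))
    R = rot.as_matrix()
    shift = target_point - R @ local_anchor
    return {name: R @ xyz + shift for name, xyz in template.items()}


def build_pocket(
    bilin: ResidueRecord,
    partners: Sequence[PartnerSpec],
    entry_id: str = "synthetic-pocket",
) -> StructureModel:
    """A bilin plus partner residues at exact prescribed contact distances.

    Each partner is placed along the first clash-free direction (candidate
    directions are deterministic, preferring the outward radial direction
    at the contacted bilin atom), so the same inputs always give the same
    structure.  Raises :class:`InfeasibleFixtureError` when no direction
    keeps all non-contact atoms clear.
    """
    used_ids = {(bilin.chain_id, bilin.seq_id)}
    bilin_coords = bilin.coords()
    bilin_center = bilin_coords.mean(axis=0)
    placed_atoms: list[np.ndarray] = []
    chains: list[tuple[ChainAnnotation, list[ResidueRecord]]] = [
        (ChainAnnotation(chain_id=bilin.chain_id), [bilin])
    ]

    from .bilin_geometry import RING_PLANES, ring_plane_normal  # full ring for stacks

    for spec in partners:
        if (spec.chain_id, spec.seq_id) in used_ids:
            raise ValueError(f"duplicate partner id {(spec.chain_id, spec.seq_id)}")
        used_ids.add((spec.chain_id, spec.seq_id))
        if spec.res_name not in _TEMPLATES:
            raise ValueError(f"no template for residue {spec.res_name!r}")
        template = _TEMPLATES[spec.res_name]

        if spec.contact_type == "pi_stack":
            if spec.res_name not in _TEMPLATE_RINGS:
                raise ValueError(f"{spec.res_name} has no aromatic ring")
            ring_names = _TEMPLATE_RINGS[spec.res_name]
            if not spec.bilin_ring:
                raise ValueError("pi_stack partner needs bilin_ring")
            normal = ring_plane_normal(bilin, RING_PLANES[spec.bilin_ring])
            ring_atoms = [f"{p}{spec.bilin_ring}" for p in ("N", "C1", "C2", "C3", "C4")]
            centroid = bilin.coords(ring_atoms).mean(axis=0)
            # stack on the side of the ring facing away from the bilin body
            if np.dot(normal, centroid - bilin_center) < 0:
                normal = -normal
            ring_local = np.array([template[n] for n in ring_names])
            local_normal = unit(
                np.cross(ring_local[1] - ring_local[0], ring_local[2] - ring_local[0])
            )
            target = centroid + spec.distance * normal
            # minimal rotation making the partner ring plane-parallel, then
            # translate its centroid onto the stacking point
            rot, _ = Rotation.align_vectors(normal[None, :], local_normal[None, :])
            R = rot.as_matrix()
            placement = {name: R @ xyz for name, xyz in template.items()}
            placed_centroid = np.mean([placement[n] for n in ring_names], axis=0)
            placement = {k: v + (target - placed_centroid) for k, v in placement.items()}
        else:
            if not (spec.bilin_atom and spec.partner_atom):
                raise ValueError(f"{spec.contact_type} partner needs bilin_atom and partner_atom")
            if spec.partner_atom not in template:
                raise ValueError(
                    f"template {spec.res_name} has no atom {spec.partner_atom!r}"
                )
            anchor = bilin.atom(spec.bilin_atom).coords
            preferred = anchor - bilin_center
            if np.linalg.norm(preferred) < 1e-6:
                preferred = np.array([0.0, 0.0, 1.0])
            preferred = unit(preferred)
            candidates = _fibonacci_directions()
            order = np.argsort(-candidates @ preferred)
            placement = None
            for idx in order:
                direction = candidates[idx]
                target = anchor + spec.distance * direction
                # the contact atom points back at the bilin; the residue body
                # trails away along +direction
                trial = _place_template(template, spec.partner_atom, target, -direction)
                trial_coords = np.array(list(trial.values()))
                # clearance against the bilin (contact pair exempt) ...
                d_bilin = np.linalg.norm(
                    trial_coords[:, None, :] - bilin_coords[None, :, :], axis=-1
                )
                names = list(trial.keys())
                contact_row = names.index(spec.partner_atom)
                contact_col = bilin.atom_names.index(spec.bilin_atom)
                mask = np.ones_like(d_bilin, dtype=bool)
                mask[contact_row, contact_col] = False
                ok = d_bilin[mask].min() >= _CLEARANCE
                # ... and against previously placed partners
                if ok and placed_atoms:
                    prev = np.array(placed_atoms)
                    d_prev = np.linalg.norm(
                        trial_coords[:, None, :] - prev[None, :, :], axis=-1
                    )
                    ok = d_prev.min() >= _CLEARANCE
                if ok:
                    placement = trial
                    break
            if placement is None:
                raise InfeasibleFixtureError(
                    f"no clash-free direction for {spec.res_name} "
                    f"{spec.partner_atom}..{spec.bilin_atom} at {spec.distance} A"
                )
            # exactness guarantee of the prescribed distance
            realized = np.linalg.norm(
                placement[spec.partner_atom] - bilin.atom(spec.bilin_atom).coords
            )
            if abs(realized - spec.distance) > 1e-9:
                raise InfeasibleFixtureError(
                    f"placement drift: {realized} != {spec.distance}"
                )

        atoms = [
            AtomSite(atom_name=name, element=_element_of(name), coords=xyz)
            for name, xyz in placement.items()
        ]
        residue = ResidueRecord(
            comp_id=spec.res_name, seq_id=spec.seq_id, chain_id=spec.chain_id, atoms=atoms
        )
        placed_atoms.extend(xyz for xyz in placement.values())
        chains.append((ChainAnnotation(chain_id=spec.chain_id), [residue]))

    merged: dict[str, tuple[ChainAnnotation, list[ResidueRecord]]] = {}
    for ann, residues in chains:
        if ann.chain_id in merged:
            merged[ann.chain_id][1].extend(residues)
        else:
            merged[ann.chain_id] = (ann, list(residues))
    return StructureModel(entry_id=entry_id, chains=list(merged.values()))
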