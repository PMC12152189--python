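"""Cylinder twist and symmetry-axis geometry of APC assemblies.

An APC cylinder is four stacked (alpha-beta)_3 rings.  Its axis is
estimated as the total-least-squares line through the four ring centroids,
where each centroid is the unweighted mean of backbone atoms (N, CA, C, O)
of the ring's polymer chains — excluding ApcC chains and any ApcE2
residues inside annotated REP-domain ranges, which thread the cylinder
interior and would bias the centers.  The twist between two cylinders is
the angle between their axes, folded into [0, 90] (the same centering rule
as the bilin angles), which makes the measure independent of the
antiparallel arrangement of the two cylinders.

The C2 symmetry axis of a dimeric complex is extracted by Kabsch-
superposing one half onto the other and reading the rotation axis and
angle off the resulting rotation matrix; rotations far from 180 degrees
are rejected as "not an approximate two-fold".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from ._geom import angle_between_deg, fold_to_quadrant, unit
from .errors import DegenerateGeometryError, NotTwoFoldError, PairingError
from .model import BACKBONE_ATOMS, StructureModel

__all__ = [
    "RingCentroid",
    "CylinderGeometry",
    "SymmetryAxis",
    "ring_centroid",
    "fit_axis",
    "cylinder_geometry",
    "twist_angle",
    "c2_axis",
]


@dataclass(frozen=True)
class RingCentroid:
    cylinder_index: int
    ring_index: int
    centroid: np.ndarray
    n_atoms: int

    def __post_init__(self) -> None:
        if self.n_atoms <= 0:
            raise ValueError("RingCentroid.n_atoms must be positive")


@dataclass(frozen=True)
class CylinderGeometry:
    """Four ring centroids and the fitted axis of one APC cylinder."""

    cylinder_index: int
    centroids: tuple[RingCentroid, RingCentroid, RingCentroid, RingCentroid]
    axis_direction: np.ndarray  # unit vector, ring 1 -> ring 4
    axis_point: np.ndarray
    fit_rms: float


@dataclass(frozen=True)
class SymmetryAxis:
    direction: np.ndarray
    point: np.ndarray
    rotation_angle: float  # degrees in (0, 180]

    def __post_init__(self) -> None:
        if not 0.0 < self.rotation_angle <= 180.0:
            raise ValueError(f"rotation_angle {self.rotation_angle} outside (0, 180]")


def ring_centroid(model: StructureModel, cylinder: int, ring: int) -> RingCentroid:
    """Backbone-atom centroid of one (alpha-beta)_3 ring.

    Includes atoms named N/CA/C/O of polymer residues in chains annotated
    with the given cylinder and ring index; ApcC chains are excluded
    entirely, and ApcE2 residues inside ``rep_domain_ranges`` are excluded.
    """
    coords = []
    for ann, residues in model.chains:
        if ann.cylinder_index != cylinder or ann.ring_index != ring:
            continue
        if ann.subunit_role == "ApcC":
            continue
        for res in residues:
            if not res.is_polymer:
                continue
            if ann.subunit_role == "ApcE2" and ann.in_rep_domain(res.seq_id):
                continue
            for atom in res.atoms:
                if atom.atom_name in BACKBONE_ATOMS:
                    coords.append(atom.coords)
    if not coords:
        raise DegenerateGeometryError(
            f"cylinder {cylinder} ring {ring}: no backbone atoms after exclusions"
        )
    pts = np.asarray(coords, dtype=float)
    return RingCentroid(
        cylinder_index=cylinder,
        ring_index=ring,
        centroid=pts.mean(axis=0),
        n_atoms=len(pts),
    )


def fit_axis(points: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line through 3-D points.

    Returns ``(direction, anchor, fit_rms)``: the anchor is the point mean,
    the direction the first principal direction of the centered points with
    its sign chosen to run from the first point toward the last, and
    ``fit_rms`` the root-mean-square perpendicular distance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("fit_axis needs at least two 3-D points")
    anchor = pts.mean(axis=0)
    centered = pts - anchor
    if np.max(np.linalg.norm(centered, axis=1)) < 1e-9:
        raise DegenerateGeometryError("fit_axis: all points coincident")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    span = pts[-1] - pts[0]
    if np.dot(direction, span) < 0:
        direction = -direction
    perp = centered - np.outer(centered @ direction, direction)
    fit_rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return unit(direction), anchor, fit_rms


def cylinder_geometry(model: StructureModel, cylinder: int) -> CylinderGeometry:
    """Centroids of rings 1-4 plus the fitted cylinder axis.

    Cylinders must have exactly four annotated rings; anything else is an
    error, not a guess.
    """
    rings_present = sorted(
        {
            ann.ring_index
            for ann, _ in model.chains
            if ann.cylinder_index == cylinder and ann.ring_index is not None
        }
    )
    if rings_present != [1, 2, 3, 4]:
        raise PairingError(
            f"cylinder {cylinder}: annotated rings {rings_present}, expected [1, 2, 3, 4]"
        )
    centroids = tuple(ring_centroid(model, cylinder, ring) for ring in (1, 2, 3, 4))
    direction, anchor, rms = fit_axis([c.centroid for c in centroids])
    return CylinderGeometry(
        cylinder_index=cylinder,
        centroids=centroids,  # ordered by ring_index
        axis_direction=direction,
        axis_point=anchor,
        fit_rms=rms,
    )


def twist_angle(axis1: np.ndarray, axis2: np.ndarray) -> float:
    """Inter-axis angle folded into [0, 90] degrees.

    The fold makes the twist independent of axis orientation, which is what
    an antiparallel cylinder pair requires: a raw inter-vector angle of 150
    degrees reports a 30-degree twist.
    """
    return fold_to_quadrant(angle_between_deg(axis1, axis2))


def _paired_ca_coords(
    model: StructureModel, chain_a: str, chain_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinates of two chains paired position-by-position over shared residue numbers."""

    def ca_map(chain_id: str) -> dict[int, np.ndarray]:
        try:
            residues = model.chain_residues(chain_id)
        except KeyError as exc:
            raise PairingError(str(exc)) from exc
        return {
            res.seq_id: res.atom("CA").coords
            for res in residues
            if res.is_polymer and res.has_atom("CA")
        }

    map_a = ca_map(chain_a)
    map_b = ca_map(chain_b)
    shared = sorted(set(map_a) & set(map_b))
    if not shared:
        raise PairingError(f"chains {chain_a}/{chain_b}: no shared residue numbers with CA")
    a = np.array([map_a[i] for i in shared])
    b = np.array([map_b[i] for i in shared])
    return a, b


def c2_axis(
    model: StructureModel,
    half_a: Iterable[str],
    half_b: Iterable[str],
    pairing: Mapping[str, str],
    min_angle: float = 150.0,
) -> SymmetryAxis:
    """Two-fold symmetry axis relating two halves of a complex.

    CA atoms of each ``pairing`` chain pair (half_a chain -> half_b chain)
    are pooled, half_a is Kabsch-superposed onto half_b, and the axis is
    the eigenvector (eigenvalue 1) of the resulting rotation; its anchor is
    the fixed point of the screw transform that minimizes translation along
    the axis.  Rotations below ``min_angle`` degrees raise
    :class:`NotTwoFoldError`.
    """
    half_a = list(half_a)
    half_b = list(half_b)
    missing = [c for c in half_a if c not in pairing]
    if missing:
        raise PairingError(f"chains {missing} of half_a missing from pairing")
    bad_targets = [pairing[c] for c in half_a if pairing[c] not in half_b]
    if bad_targets:
        raise PairingError(f"pairing targets {bad_targets} not in half_b")

    mob_parts, tgt_parts = [], []
    for chain in half_a:
        a, b = _paired_ca_coords(model, chain, pairing[chain])
        mob_parts.append(a)
        tgt_parts.append(b)
    mobile = np.vstack(mob_parts)
    target = np.vstack(tgt_parts)

    from .docking_assembly import kabsch_superpose  # local import: avoids cycle

    transform = kabsch_superpose(mobile, target)
    R, t = transform.rotation, transform.translation

    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = min(float(np.degrees(np.linalg.norm(rotvec))), 180.0)
    if angle < min_angle:
        raise NotTwoFoldError(
            f"superposition rotation is {angle:.1f} deg; not an approximate two-fold "
            f"(threshold {min_angle} deg)"
        )
    direction = unit(rotvec, "rotation axis")

    # Fixed point: solve (I - R) p = t restricted to the plane normal to the
    # axis (the component of t along the axis is the irreducible screw pitch).
    t_perp = t - np.dot(t, direction) * direction
    point, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return SymmetryAxis(direction=direction, point=point, rotation_angle=angle)
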