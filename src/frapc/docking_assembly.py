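"""Template-guided composite assembly and pigment distance networks.

A mesoscale model of the far-red antenna–photosystem arrangement is built
by rigid-body superposition: each component structure (an FR-APC
bicylinder, FR-PSII dimers) is anchored onto a lower-resolution template
supercomplex through a user-supplied chain pairing, pooling CA atoms over
shared residue numbers and solving the least-squares rotation/translation
(Kabsch).  On the placed composite the quantities of interest are pigment
inventories per subunit group and pigment–pigment distances — in
particular the edge-to-edge distance, the minimum heavy-atom separation
between two pigments' conjugated systems, which is the distance relevant
to excitation energy transfer.

For chlorophylls the saturated phytyl tail is excluded from the
edge-to-edge atom set by default (it is not part of the conjugated
system); for bilins all heavy atoms are retained, with a switch to drop
the propionate arms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InsufficientAnchorError, PairingError
from .model import ResidueRecord, StructureModel
from .structure_io import select_ligands

__all__ = [
    "RigidTransform",
    "CompositeAssembly",
    "PigmentDistance",
    "kabsch_superpose",
    "fit_component_to_template",
    "edge_to_edge",
    "center_to_center",
    "pigment_inventory",
    "CHLOROPHYLL_COMP_IDS",
    "BILIN_PROPIONATE_ATOMS",
]

#: Component ids treated as chlorophylls for the default edge filter.
CHLOROPHYLL_COMP_IDS = frozenset({"CLA", "CHL", "CL0", "F6C", "G9R", "CL7"})

#: Phytyl-tail atoms of chlorophyll components: plain C1..C20 (no ring
#: letter) plus the ester oxygens linking the tail to the macrocycle.
_PHYTYL_PATTERN = re.compile(r"^C([1-9]|1[0-9]|20)$")
_PHYTYL_EXTRA = frozenset({"O1", "O2", "O1A", "O2A"})

#: Propionate-arm atoms of the bilin (rings B and C), excluded only when
#: ``exclude_propionates=True``.
BILIN_PROPIONATE_ATOMS = frozenset(
    {"CAB", "CBB", "CGB", "O1B", "O2B", "CAC", "CBC", "CGC", "O1C", "O2C"}
)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t with its fit quality."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float = 0.0
    n_pairs: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("RigidTransform needs a 3x3 rotation and a 3-vector translation")
        if abs(np.linalg.det(R) - 1.0) > 1e-9 or np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be proper orthonormal (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation + translation mapping ``mobile`` onto ``target``.

    Reflections are forbidden; the reported rmsd is over the given pairing.
    Requires n >= 3 non-collinear pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be equal-shape (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError(f"kabsch_superpose needs >= 3 pairs, got {n}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    mob_c = mobile - cm
    tgt_c = target - ct
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("kabsch_superpose: mobile points are (near-)collinear")
    rot, rssd = Rotation.align_vectors(tgt_c, mob_c)
    R = rot.as_matrix()
    t = ct - R @ cm
    rmsd = float(rssd / np.sqrt(n))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def _pooled_ca_pairs(
    component: StructureModel, template: StructureModel, chain_pairing: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    mob_parts, tgt_parts = [], []
    for comp_chain, tmpl_chain in chain_pairing.items():
        if comp_chain not in component.chain_ids:
            raise PairingError(f"component has no chain {comp_chain!r}")
        if tmpl_chain not in template.chain_ids:
            raise PairingError(f"template has no chain {tmpl_chain!r}")

        def ca_map(model: StructureModel, chain: str) -> dict[int, np.ndarray]:
            return {
                r.seq_id: r.atom("CA").coords
                for r in model.chain_residues(chain)
                if r.is_polymer and r.has_atom("CA")
            }

        comp_ca = ca_map(component, comp_chain)
        tmpl_ca = ca_map(template, tmpl_chain)
        shared = sorted(set(comp_ca) & set(tmpl_ca))
        mob_parts.extend(comp_ca[i] for i in shared)
        tgt_parts.extend(tmpl_ca[i] for i in shared)
    return np.array(mob_parts, dtype=float), np.array(tgt_parts, dtype=float)


def fit_component_to_template(
    component: StructureModel,
    template: StructureModel,
    chain_pairing: Mapping[str, str],
    min_pairs: int = 50,
) -> RigidTransform:
    """Rigid transform placing ``component`` into the template frame.

    CA atoms of each paired chain are matched position-by-position over
    shared residue numbers and pooled into one Kabsch superposition.  The
    component is never mutated; apply the returned transform lazily via
    :meth:`StructureModel.transformed` or :class:`CompositeAssembly`.
    """
    mobile, target = _pooled_ca_pairs(component, template, chain_pairing)
    if len(mobile) < min_pairs:
        raise InsufficientAnchorError(
            f"only {len(mobile)} pooled CA pairs (< {min_pairs}): insufficient anchor"
        )
    return kabsch_superpose(mobile, target)


@dataclass(frozen=True)
class PigmentDistance:
    pigment_a: tuple[str, str, str, int]  # (component_role, chain_id, comp_id, seq_id)
    pigment_b: tuple[str, str, str, int]
    distance: float
    atom_pair: tuple[str, str]
    metric: str  # "edge_to_edge" | "center_to_center"


def _retained_atoms(residue: ResidueRecord, exclude_propionates: bool) -> list:
    """Heavy atoms that count as a pigment's conjugated 'edge'."""
    atoms = residue.heavy_atoms()
    if residue.comp_id in CHLOROPHYLL_COMP_IDS:
        atoms = [
            a
            for a in atoms
            if not _PHYTYL_PATTERN.match(a.atom_name) and a.atom_name not in _PHYTYL_EXTRA
        ]
    elif exclude_propionates:
        atoms = [a for a in atoms if a.atom_name not in BILIN_PROPIONATE_ATOMS]
    return atoms


def edge_to_edge(
    a: ResidueRecord,
    b: ResidueRecord,
    exclude_propionates: bool = False,
    roles: tuple[str, str] = ("", ""),
) -> PigmentDistance:
    """Minimum heavy-atom distance between two pigments' retained atom sets."""
    atoms_a = _retained_atoms(a, exclude_propionates)
    atoms_b = _retained_atoms(b, exclude_propionates)
    for res, atoms in ((a, atoms_a), (b, atoms_b)):
        if not atoms:
            raise DegenerateGeometryError(
                f"residue {res.comp_id} {res.chain_id}{res.seq_id}: no atoms survive the edge filter"
            )
    da = cdist(
        np.array([x.coords for x in atoms_a]), np.array([x.coords for x in atoms_b])
    )
    i, j = np.unravel_index(np.argmin(da), da.shape)
    return PigmentDistance(
        pigment_a=(roles[0], a.chain_id, a.comp_id, a.seq_id),
        pigment_b=(roles[1], b.chain_id, b.comp_id, b.seq_id),
        distance=float(da[i, j]),
        atom_pair=(atoms_a[i].atom_name, atoms_b[j].atom_name),
        metric="edge_to_edge",
    )


def center_to_center(
    a: ResidueRecord,
    b: ResidueRecord,
    exclude_propionates: bool = False,
    roles: tuple[str, str] = ("", ""),
) -> PigmentDistance:
    """Distance between the geometric centers of the retained atom sets."""
    ca = np.mean([x.coords for x in _retained_atoms(a, exclude_propionates)], axis=0)
    cb = np.mean([x.coords for x in _retained_atoms(b, exclude_propionates)], axis=0)
    return PigmentDistance(
        pigment_a=(roles[0], a.chain_id, a.comp_id, a.seq_id),
        pigment_b=(roles[1], b.chain_id, b.comp_id, b.seq_id),
        distance=float(np.linalg.norm(ca - cb)),
        atom_pair=("<center>", "<center>"),
        metric="center_to_center",
    )


@dataclass
class CompositeAssembly:
    """Component models placed by rigid transforms into a template frame.

    Chains of placed components are renamed ``"<role>:<original>"`` so the
    merged model is collision-free and the renaming is reversible.
    """

    template_id: str
    components: list[tuple[StructureModel, RigidTransform, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def add(self, model: StructureModel, transform: RigidTransform, role: str) -> None:
        if any(role == r for _, _, r in self.components):
            raise ValueError(f"component role {role!r} already present")
        self.components.append((model, transform, role))

    def placed_models(self) -> list[tuple[str, StructureModel]]:
        """Each component transformed into the template frame, chains renamed."""
        out = []
        for model, transform, role in self.components:
            placed = model.transformed(transform.rotation, transform.translation)
            renaming = {cid: f"{role}:{cid}" for cid in placed.chain_ids}
            out.append((role, placed.renamed_chains(renaming)))
        return out

    def to_model(self, entry_id: Optional[str] = None) -> StructureModel:
        chains = []
        for _, placed in self.placed_models():
            chains.extend(placed.chains)
        return StructureModel(entry_id=entry_id or f"composite-{self.template_id}", chains=chains)

    def pigments(self, comp_ids: Iterable[str]) -> list[tuple[str, ResidueRecord]]:
        """(component_role, placed ligand residue) for every matching ligand."""
        out = []
        for role, placed in self.placed_models():
            for res in select_ligands(placed, comp_ids):
                out.append((role, res))
        return out

    def pigment_distances(
        self,
        comp_ids_a: Iterable[str],
        comp_ids_b: Iterable[str],
        metric: str = "edge_to_edge",
        exclude_propionates: bool = False,
    ) -> list[PigmentDistance]:
        """All cross distances between two pigment selections on the composite."""
        func = edge_to_edge if metric == "edge_to_edge" else center_to_center
        group_a = self.pigments(comp_ids_a)
        group_b = self.pigments(comp_ids_b)
        out = []
        for role_a, res_a in group_a:
            for role_b, res_b in group_b:
                if role_a == role_b and res_a.chain_id == res_b.chain_id and res_a.seq_id == res_b.seq_id:
                    continue
                out.append(
                    func(
                        res_a,
                        res_b,
                        exclude_propionates=exclude_propionates,
                        roles=(role_a, role_b),
                    )
                )
        return sorted(out, key=lambda d: d.distance)


def pigment_inventory(
    model: StructureModel,
    grouping: Mapping[str, str],
    comp_ids: Iterable[str] = ("CYC",),
) -> dict[str, int]:
    """Count selected ligands per subunit group.

    ``grouping`` maps subunit roles to group labels, e.g. every far-red
    alpha-type role (ApcD2, ApcD3, ApcD5, ApcE2) to ``"alpha-site"``.
    Roles not in the grouping count under ``"other"``.
    """
    counts: dict[str, int] = {label: 0 for label in grouping.values()}
    for res in select_ligands(model, comp_ids):
        role = model.annotation(res.chain_id).subunit_role
        label = grouping.get(role, "other")
        counts[label] = counts.get(label, 0) + 1
    return counts
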