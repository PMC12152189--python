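"""Bilin ring-plane planarity and methine-bridge stereochemistry.

Phycocyanobilin (PDB component CYC) is an open-chain tetrapyrrole: four
pyrrole rings A-D joined by methine bridge carbons (CHB between A and B,
CHC between B and C, CHD between C and D).  How far rings A and D tilt out
of the plane of the central B/C pair governs the conjugation length and
hence the absorption of the pigment, so the planarity statistic computed
here is the per-bilin triple of centered inter-ring-plane angles
(theta_AB, theta_BC, theta_CD).

Each ring plane is defined by a three-atom triplet (ring A: NA, C3A, C4A,
and the parallel definitions for B, C, D); the normal is the normalized
cross product of two in-plane vectors, the inter-plane angle the arccosine
of the normal dot product, and angles above 90 degrees are centered to
180 - angle so the result is sign-gauge invariant in [0, 90].

Methine-bridge stereochemistry (labels like "ZZZ,ssa") is classified from
two torsions per bridge X-CH-Y:

* configuration (Z/E): torsion N_X - C4X - CH - C1Y about the bridge
  double bond; |torsion| < 90 deg -> Z;
* conformation (syn/anti): torsion C4X - CH - C1Y - N_Y about the
  ring-adjacent single bond; |torsion| < 90 deg -> syn (s).

Torsions within 5 degrees of the 90-degree decision boundary set a
boundary-warning flag on the emitted label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._geom import angle_between_deg, dihedral_deg, fold_to_quadrant, plane_normal, unit
from .errors import DegenerateGeometryError, FrapcError, MissingAtomError
from .model import ResidueRecord, StructureModel
from .structure_io import select_ligands

__all__ = [
    "RING_PLANES",
    "BRIDGES",
    "RingPlaneDefinition",
    "BilinChromophore",
    "PlanarityRecord",
    "ConformerLabel",
    "ring_plane_normal",
    "interplane_angle",
    "planarity_profile",
    "classify_conformer",
    "profile_to_frame",
]

#: Degrees around the 90-degree Z/E and syn/anti cut-off inside which a
#: classification is flagged as boundary-ambiguous.
BOUNDARY_MARGIN = 5.0


@dataclass(frozen=True)
class RingPlaneDefinition:
    """A pyrrole ring plane as an ordered three-atom triplet."""

    ring_id: str
    atom_triplet: tuple[str, str, str]


#: The four ring-plane definitions.  These triplets are the package's
#: fixed convention; pass custom definitions only for non-standard ligands.
RING_PLANES: dict[str, RingPlaneDefinition] = {
    "A": RingPlaneDefinition("A", ("NA", "C3A", "C4A")),
    "B": RingPlaneDefinition("B", ("NB", "C3B", "C4B")),
    "C": RingPlaneDefinition("C", ("NC", "C3C", "C4C")),
    "D": RingPlaneDefinition("D", ("ND", "C3D", "C4D")),
}


@dataclass(frozen=True)
class BridgeDefinition:
    """One methine bridge: its carbon and the two classification torsions."""

    name: str  # "AB", "BC", "CD"
    bridge_atom: str
    configuration_torsion: tuple[str, str, str, str]
    conformation_torsion: tuple[str, str, str, str]


#: Methine bridges A-B, B-C, C-D with the torsion atom quadruples used for
#: Z/E (about C4X-CH) and syn/anti (about CH-C1Y) classification.
BRIDGES: tuple[BridgeDefinition, ...] = (
    BridgeDefinition("AB", "CHB", ("NA", "C4A", "CHB", "C1B"), ("C4A", "CHB", "C1B", "NB")),
    BridgeDefinition("BC", "CHC", ("NB", "C4B", "CHC", "C1C"), ("C4B", "CHC", "C1C", "NC")),
    BridgeDefinition("CD", "CHD", ("NC", "C4C", "CHD", "C1D"), ("C4C", "CHD", "C1D", "ND")),
)


@dataclass
class BilinChromophore:
    """One CYC ligand with resolved ring-plane normals and bridge atoms."""

    residue: ResidueRecord
    plane_normals: dict[str, np.ndarray]

    @classmethod
    def from_residue(cls, residue: ResidueRecord) -> "BilinChromophore":
        normals = {
            ring_id: ring_plane_normal(residue, definition)
            for ring_id, definition in RING_PLANES.items()
        }
        return cls(residue=residue, plane_normals=normals)


@dataclass(frozen=True)
class PlanarityRecord:
    """Centered inter-plane angles of one bilin, degrees in [0, 90]."""

    structure_id: str
    chain_id: str
    seq_id: int
    subunit_role: str
    theta_AB: float
    theta_BC: float
    theta_CD: float
    conformer_label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("theta_AB", "theta_BC", "theta_CD"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name}={v} outside [0, 90]")


@dataclass(frozen=True)
class ConformerLabel:
    """Methine-bridge stereodescriptor, e.g. ZZZ,ssa."""

    configuration: tuple[str, str, str]  # Z/E per bridge AB, BC, CD
    conformation: tuple[str, str, str]  # s/a per bridge AB, BC, CD
    boundary_warning: bool = False
    torsions: dict = field(default_factory=dict, compare=False)

    @property
    def label(self) -> str:
        return "".join(self.configuration) + "," + "".join(self.conformation)

    def __str__(self) -> str:
        return self.label


def ring_plane_normal(residue: ResidueRecord, ring: RingPlaneDefinition) -> np.ndarray:
    """Unit normal of one pyrrole ring plane from its defining atom triplet."""
    try:
        p1, p2, p3 = (residue.atom(name).coords for name in ring.atom_triplet)
    except MissingAtomError as exc:
        raise MissingAtomError(f"ring {ring.ring_id}: {exc}") from exc
    try:
        return plane_normal(p1, p2, p3)
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(
            f"ring {ring.ring_id} of {residue.comp_id} {residue.chain_id}{residue.seq_id}: {exc}"
        ) from exc


def interplane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Centered angle between two plane normals, degrees in [0, 90].

    theta = arccos(clamp(n1.n2 / (|n1||n2|), -1, 1)); values above 90 are
    mapped to 180 - theta, making the result invariant under negation of
    either normal.
    """
    return fold_to_quadrant(angle_between_deg(unit(n1, "n1"), unit(n2, "n2")))


def _bridge_torsions(residue: ResidueRecord, bridge: BridgeDefinition) -> tuple[float, float]:
    def torsion(names: tuple[str, str, str, str]) -> float:
        try:
            pts = [residue.atom(n).coords for n in names]
        except MissingAtomError as exc:
            raise MissingAtomError(f"bridge {bridge.name}: {exc}") from exc
        return dihedral_deg(*pts)

    return torsion(bridge.configuration_torsion), torsion(bridge.conformation_torsion)


def classify_conformer(bilin: BilinChromophore) -> ConformerLabel:
    """Assign the Z/E + syn/anti stereodescriptor of a bilin.

    Classification is purely geometric: |torsion| < 90 degrees means Z
    (configuration) or syn (conformation).  A torsion within
    ``BOUNDARY_MARGIN`` of 90 degrees sets ``boundary_warning``.
    """
    configuration: list[str] = []
    conformation: list[str] = []
    torsions: dict[str, tuple[float, float]] = {}
    warn = False
    for bridge in BRIDGES:
        cfg_t, conf_t = _bridge_torsions(bilin.residue, bridge)
        torsions[bridge.name] = (cfg_t, conf_t)
        configuration.append("Z" if abs(cfg_t) < 90.0 else "E")
        conformation.append("s" if abs(conf_t) < 90.0 else "a")
        for t in (cfg_t, conf_t):
            if abs(abs(t) - 90.0) < BOUNDARY_MARGIN:
                warn = True
    return ConformerLabel(
        configuration=tuple(configuration),
        conformation=tuple(conformation),
        boundary_warning=warn,
        torsions=torsions,
    )


def planarity_profile(
    model: StructureModel,
    comp_ids: Iterable[str] = ("CYC",),
    classify: bool = True,
) -> tuple[list[PlanarityRecord], list[tuple[str, str]]]:
    """Per-bilin centered inter-plane angles for every selected ligand.

    Returns ``(records, skipped)`` where ``skipped`` lists
    ``(residue description, reason)`` for ligands whose rings could not be
    resolved — they are reported, never silently dropped.
    """
    records: list[PlanarityRecord] = []
    skipped: list[tuple[str, str]] = []
    for residue in select_ligands(model, comp_ids):
        label = f"{residue.comp_id} {residue.chain_id}{residue.seq_id}"
        try:
            bilin = BilinChromophore.from_residue(residue)
            conformer = None
            if classify:
                conformer = classify_conformer(bilin).label
            records.append(
                PlanarityRecord(
                    structure_id=model.entry_id,
                    chain_id=residue.chain_id,
                    seq_id=residue.seq_id,
                    subunit_role=model.annotation(residue.chain_id).subunit_role,
                    theta_AB=interplane_angle(bilin.plane_normals["A"], bilin.plane_normals["B"]),
                    theta_BC=interplane_angle(bilin.plane_normals["B"], bilin.plane_normals["C"]),
                    theta_CD=interplane_angle(bilin.plane_normals["C"], bilin.plane_normals["D"]),
                    conformer_label=conformer,
                )
            )
        except FrapcError as exc:
            skipped.append((label, str(exc)))
    return records, skipped


def profile_to_frame(records: Iterable[PlanarityRecord]) -> pd.DataFrame:
    """Planarity records as a tidy DataFrame (one row per bilin)."""
    return pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "chain_id": r.chain_id,
                "seq_id": r.seq_id,
                "subunit_role": r.subunit_role,
                "theta_AB": r.theta_AB,
                "theta_BC": r.theta_BC,
                "theta_CD": r.theta_CD,
                "conformer_label": r.conformer_label,
            }
            for r in records
        ]
    )
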