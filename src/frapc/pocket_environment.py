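"""Geometric detection of bilin-pocket interactions.

The protein micro-environment of each bilin — hydrogen bonds to the ring
nitrogens and keto oxygens, salt bridges from Arg/Lys/His to the
propionate carboxylates, aromatic stacking on the pyrrole rings, and
residual steric contacts — is what differentiates paralogous pigment
sites with identical chromophores.  Detection here is purely geometric
and heavy-atom based (cryo-EM models carry no hydrogens): an H-bond is a
donor/acceptor N/O pair within a distance cut-off, a salt bridge a
carboxylate-O/charged-N pair, a pi-stack a ring-centroid pair that is
both close and near-parallel (normal angle folded into [0, 90]), and a
steric contact any remaining heavy-atom pair under the steric cut-off.

The paper-style comparisons (same site in two paralogues) are set
differences over (contact type, partner residue) keys plus distance
deltas on the shared contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._geom import angle_between_deg, fold_to_quadrant, plane_normal
from .errors import DegenerateGeometryError
from .model import ResidueRecord, StructureModel

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "PocketComparison",
    "detect_contacts",
    "compare_pockets",
    "contacts_to_frame",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Distance/angle cut-offs, Angstrom and degrees.

    Defaults follow common structural-biology practice; the source study
    reports its interactions qualitatively, so every cut-off here is
    config, not science.
    """

    hbond_max_da: float = 3.5
    saltbridge_max: float = 4.0
    stack_max_centroid: float = 5.5
    stack_max_normal_angle: float = 30.0
    steric_max: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "hbond_max_da",
            "saltbridge_max",
            "stack_max_centroid",
            "stack_max_normal_angle",
            "steric_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ContactRecord:
    bilin_id: tuple[str, int]  # (chain_id, seq_id)
    partner_chain: str
    partner_comp: str
    partner_seq: int
    partner_atom: str
    bilin_atom: str
    contact_type: str  # hbond | salt_bridge | pi_stack | steric
    distance: float
    geometry_note: str = ""

    @property
    def partner(self) -> tuple[str, str, str]:
        return (self.partner_chain, f"{self.partner_comp}{self.partner_seq}", self.partner_atom)


# ---------------------------------------------------------------------------
# Minimal chemistry tables (standard residues + the CYC bilin); heavy atoms
# only, no protonation inference.
# ---------------------------------------------------------------------------

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "MET": set(),
}
_CHARGED_N = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}

_AROMATIC_RINGS = {
    "PHE": [("6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "HIS": [("5", ("CG", "ND1", "CD2", "CE1", "NE2"))],
    "TRP": [
        ("5", ("CG", "CD1", "NE1", "CE2", "CD2")),
        ("6", ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    ],
}

#: Bilin polar atoms.  Ring nitrogens donate; any oxygen accepts.  The
#: propionate carboxylate oxygens double as salt-bridge partners.
BILIN_DONOR_N = frozenset({"NA", "NB", "NC", "ND"})
BILIN_PROPIONATE_O = frozenset({"O1B", "O2B", "O1C", "O2C"})

#: Full five-membered pyrrole rings of the bilin (for stacking centroids).
BILIN_RINGS = {
    ring: (f"N{ring}", f"C1{ring}", f"C2{ring}", f"C3{ring}", f"C4{ring}")
    for ring in ("A", "B", "C", "D")
}


def _protein_polar_atoms(residue: ResidueRecord) -> list[tuple[str, str]]:
    """(atom_name, role) with role in {donor, acceptor, both} for one protein residue."""
    donors = set(_SIDECHAIN_DONORS.get(residue.comp_id, set()))
    acceptors = set(_SIDECHAIN_ACCEPTORS.get(residue.comp_id, set()))
    donors.add("N")  # backbone amide
    acceptors.add("O")  # backbone carbonyl
    out = []
    for atom in residue.atoms:
        name = atom.atom_name
        if name in donors and name in acceptors:
            out.append((name, "both"))
        elif name in donors:
            out.append((name, "donor"))
        elif name in acceptors:
            out.append((name, "acceptor"))
    return out


def _ring_geometry(
    residue: ResidueRecord, atom_names: Iterable[str]
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """(centroid, unit normal) of a ring, or None if atoms are missing/degenerate."""
    names = [n for n in atom_names if residue.has_atom(n)]
    if len(names) < 3:
        return None
    pts = residue.coords(names)
    try:
        normal = plane_normal(pts[0], pts[1], pts[2])
    except DegenerateGeometryError:
        return None
    return pts.mean(axis=0), normal


def detect_contacts(
    model: StructureModel,
    bilin: ResidueRecord,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """All protein contacts of one bilin under the given criteria.

    Records are deterministic and sorted by (contact_type, distance,
    partner).  Partner residues with unresolvable ring geometry are simply
    not considered for stacking; nothing is fatal.
    """
    bilin_heavy = bilin.heavy_atoms()
    bilin_id = (bilin.chain_id, bilin.seq_id)
    records: list[ContactRecord] = []
    classified_pairs: set[tuple[str, int, str, str, str]] = set()

    bilin_rings = {
        ring: geom
        for ring, names in BILIN_RINGS.items()
        if (geom := _ring_geometry(bilin, names)) is not None
    }

    max_cut = max(
        criteria.hbond_max_da,
        criteria.saltbridge_max,
        criteria.steric_max,
        criteria.stack_max_centroid + 3.0,  # ring atoms sit ~1.4-2.4 A off the centroid
    )
    bilin_coords = np.array([a.coords for a in bilin_heavy])

    for ann, residue in model.residues():
        if not residue.is_polymer:
            continue
        if residue.chain_id == bilin.chain_id and residue.seq_id == bilin.seq_id:
            continue
        partner_heavy = residue.heavy_atoms()
        if not partner_heavy:
            continue
        partner_coords = np.array([a.coords for a in partner_heavy])
        dmat = np.linalg.norm(
            bilin_coords[:, None, :] - partner_coords[None, :, :], axis=-1
        )
        if dmat.min() > max_cut:
            continue
        partner_index = {a.atom_name: k for k, a in enumerate(partner_heavy)}
        bilin_index = {a.atom_name: k for k, a in enumerate(bilin_heavy)}

        def pair_key(p_atom: str, b_atom: str, ctype: str):
            return (residue.chain_id, residue.seq_id, p_atom, b_atom, ctype)

        def emit(ctype: str, b_atom: str, p_atom: str, dist: float, note: str = ""):
            records.append(
                ContactRecord(
                    bilin_id=bilin_id,
                    partner_chain=residue.chain_id,
                    partner_comp=residue.comp_id,
                    partner_seq=residue.seq_id,
                    partner_atom=p_atom,
                    bilin_atom=b_atom,
                    contact_type=ctype,
                    distance=float(dist),
                    geometry_note=note,
                )
            )

        # -- salt bridges first (they take precedence over plain H-bonds):
        #    propionate carboxylate O vs Arg/Lys/His charged N
        charged = _CHARGED_N.get(residue.comp_id, set())
        salt_pairs: set[tuple[str, str]] = set()
        for b_name in BILIN_PROPIONATE_O:
            i = bilin_index.get(b_name)
            if i is None:
                continue
            for p_name in charged:
                k = partner_index.get(p_name)
                if k is None:
                    continue
                d = dmat[i, k]
                if d <= criteria.saltbridge_max:
                    emit("salt_bridge", b_name, p_name, d)
                    salt_pairs.add((p_name, b_name))
                    classified_pairs.add(
                        (residue.chain_id, residue.seq_id, p_name, b_name, "polar")
                    )

        # -- hydrogen bonds: bilin N/O vs protein N/O, donor/acceptor compatible
        for b_atom in bilin_heavy:
            b_role = None
            if b_atom.atom_name in BILIN_DONOR_N:
                b_role = "donor"
            elif b_atom.element.upper() == "O":
                b_role = "acceptor"
            if b_role is None:
                continue
            for p_name, p_role in _protein_polar_atoms(residue):
                k = partner_index.get(p_name)
                if k is None:
                    continue
                if (p_name, b_atom.atom_name) in salt_pairs:
                    continue
                compatible = (
                    p_role == "both"
                    or b_role == "both"
                    or p_role != b_role
                )
                d = dmat[bilin_index[b_atom.atom_name], k]
                if compatible and d <= criteria.hbond_max_da:
                    emit("hbond", b_atom.atom_name, p_name, d)
                    classified_pairs.add(
                        (residue.chain_id, residue.seq_id, p_name, b_atom.atom_name, "polar")
                    )

        # -- pi stacking: bilin ring vs aromatic side-chain ring
        for ring_label, ring_names in _AROMATIC_RINGS.get(residue.comp_id, []):
            geom = _ring_geometry(residue, ring_names)
            if geom is None:
                continue
            p_centroid, p_normal = geom
            for b_ring, (b_centroid, b_normal) in bilin_rings.items():
                d = float(np.linalg.norm(p_centroid - b_centroid))
                if d > criteria.stack_max_centroid:
                    continue
                normal_angle = fold_to_quadrant(angle_between_deg(b_normal, p_normal))
                if normal_angle <= criteria.stack_max_normal_angle:
                    emit(
                        "pi_stack",
                        f"ring {b_ring}",
                        f"ring{ring_label}",
                        d,
                        note=f"normal_angle={normal_angle:.1f} deg",
                    )

        # -- steric: closest unclassified heavy-atom pair, if under the cut-off
        best = None
        for i, b_atom in enumerate(bilin_heavy):
            for k, p_atom in enumerate(partner_heavy):
                if (
                    residue.chain_id,
                    residue.seq_id,
                    p_atom.atom_name,
                    b_atom.atom_name,
                    "polar",
                ) in classified_pairs:
                    continue
                d = dmat[i, k]
                if d <= criteria.steric_max and (best is None or d < best[0]):
                    best = (d, b_atom.atom_name, p_atom.atom_name)
        if best is not None:
            emit("steric", best[1], best[2], best[0])

    records.sort(
        key=lambda r: (r.contact_type, r.distance, r.partner_chain, r.partner_seq, r.partner_atom)
    )
    return records


@dataclass
class PocketComparison:
    """Paired difference of two pockets' contact sets."""

    only_in_a: list[tuple[str, str, int]] = field(default_factory=list)
    only_in_b: list[tuple[str, str, int]] = field(default_factory=list)
    shared: list[tuple[tuple[str, str, int], float, float]] = field(default_factory=list)

    @property
    def is_identical(self) -> bool:
        return not self.only_in_a and not self.only_in_b


def _contact_keys(records: Iterable[ContactRecord]) -> dict[tuple[str, str, int], float]:
    """(contact_type, partner residue name, partner residue number) -> min distance."""
    keys: dict[tuple[str, str, int], float] = {}
    for r in records:
        key = (r.contact_type, r.partner_comp, r.partner_seq)
        keys[key] = min(keys.get(key, np.inf), r.distance)
    return keys


def compare_pockets(
    records_a: Iterable[ContactRecord], records_b: Iterable[ContactRecord]
) -> PocketComparison:
    """Set-difference of (contact type, partner residue) keys plus distance
    deltas for shared contacts — the paper-style paralogue comparison."""
    keys_a = _contact_keys(records_a)
    keys_b = _contact_keys(records_b)
    return PocketComparison(
        only_in_a=sorted(set(keys_a) - set(keys_b)),
        only_in_b=sorted(set(keys_b) - set(keys_a)),
        shared=sorted(
            (key, keys_a[key], keys_b[key]) for key in set(keys_a) & set(keys_b)
        ),
    )


def contacts_to_frame(records: Iterable[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bilin_chain": r.bilin_id[0],
                "bilin_seq": r.bilin_id[1],
                "bilin_atom": r.bilin_atom,
                "partner_chain": r.partner_chain,
                "partner_comp": r.partner_comp,
                "partner_seq": r.partner_seq,
                "partner_atom": r.partner_atom,
                "contact_type": r.contact_type,
                "distance": r.distance,
                "geometry_note": r.geometry_note,
            }
            for r in records
        ]
    )
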