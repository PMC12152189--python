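"""In-memory structure model.

A :class:`StructureModel` is a light hierarchical container
(chains -> residues -> atoms) decoupled from any particular file format.
Chains carry a :class:`ChainAnnotation` assigning each one a biological
role (ApcA, ApcB2, ApcE2, ...), an APC cylinder index and an
(alpha-beta)_3 ring index, plus the residue ranges of the ApcE2 REP
domains that the cylinder-axis calculation must exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import MissingAtomError

#: Subunit roles recognised by the annotation layer.  "other" is the
#: default for unmapped chains.
KNOWN_ROLES = frozenset(
    {
        "ApcA", "ApcB", "ApcB2", "ApcC", "ApcD1", "ApcD2", "ApcD3", "ApcD5",
        "ApcE", "ApcE2", "ApcF", "ApcF2", "other",
    }
)

#: Conventional protein backbone atom names (CB deliberately excluded).
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomSite:
    """One atom with PDB-style nomenclature and Cartesian coordinates in Angstrom."""

    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def moved_to(self, coords: np.ndarray) -> "AtomSite":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class ResidueRecord:
    """One residue (polymer or ligand) and its atoms."""

    comp_id: str
    seq_id: int
    chain_id: str
    atoms: list[AtomSite]
    is_polymer: bool = True

    def __post_init__(self) -> None:
        if not self.comp_id:
            raise ValueError("comp_id must be non-empty")
        names = [a.atom_name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"residue {self.chain_id}/{self.comp_id} {self.seq_id}: duplicate atom names {dup}"
            )

    def __repr__(self) -> str:  # compact: residues can hold many atoms
        return (
            f"ResidueRecord({self.comp_id} {self.chain_id}{self.seq_id}, "
            f"{len(self.atoms)} atoms)"
        )

    @property
    def atom_names(self) -> list[str]:
        return [a.atom_name for a in self.atoms]

    def has_atom(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atoms)

    def atom(self, name: str) -> AtomSite:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise MissingAtomError(
            f"atom {name!r} missing from residue {self.comp_id} {self.chain_id}{self.seq_id}"
        )

    def coords(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        """Coordinates as an (n, 3) array; with ``names``, in that order."""
        if names is None:
            return np.array([a.coords for a in self.atoms], dtype=float)
        return np.array([self.atom(n).coords for n in names], dtype=float)

    def heavy_atoms(self) -> list[AtomSite]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ResidueRecord":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(
            self, atoms=[a.moved_to(R @ a.coords + t) for a in self.atoms]
        )


@dataclass
class ChainAnnotation:
    """Biological role and cylinder/ring membership of one chain."""

    chain_id: str
    subunit_role: str = "other"
    cylinder_index: Optional[int] = None
    ring_index: Optional[int] = None
    rep_domain_ranges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ring_index is not None and self.ring_index not in (1, 2, 3, 4):
            raise ValueError(f"chain {self.chain_id}: ring_index must be 1-4, got {self.ring_index}")
        ranges = sorted((int(a), int(b)) for a, b in self.rep_domain_ranges)
        for (a1, b1), (a2, _b2) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise ValueError(
                    f"chain {self.chain_id}: overlapping rep_domain_ranges {(a1, b1)} and ({a2}, ...)"
                )
        self.rep_domain_ranges = ranges

    def in_rep_domain(self, seq_id: int) -> bool:
        return any(a <= seq_id <= b for a, b in self.rep_domain_ranges)


@dataclass
class StructureModel:
    """A whole (first-model) structure: annotated chains of residues."""

    entry_id: str
    chains: list[tuple[ChainAnnotation, list[ResidueRecord]]]

    def __post_init__(self) -> None:
        ids = [ann.chain_id for ann, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain_ids in {self.entry_id}: {sorted(ids)}")
        for ann, residues in self.chains:
            for r in residues:
                if r.chain_id != ann.chain_id:
                    raise ValueError(
                        f"residue {r!r} carries chain_id {r.chain_id!r} inside chain {ann.chain_id!r}"
                    )

    # -- access ---------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return [ann.chain_id for ann, _ in self.chains]

    def annotation(self, chain_id: str) -> ChainAnnotation:
        for ann, _ in self.chains:
            if ann.chain_id == chain_id:
                return ann
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    def chain_residues(self, chain_id: str) -> list[ResidueRecord]:
        for ann, residues in self.chains:
            if ann.chain_id == chain_id:
                return residues
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    def residues(self) -> Iterator[tuple[ChainAnnotation, ResidueRecord]]:
        for ann, residues in self.chains:
            for r in residues:
                yield ann, r

    def atom_count(self) -> int:
        return sum(len(r.atoms) for _, r in self.residues())

    def all_coords(self) -> np.ndarray:
        rows = [r.coords() for _, r in self.residues() if r.atoms]
        if not rows:
            return np.empty((0, 3))
        return np.vstack(rows)

    # -- manipulation ---------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with every coordinate mapped x -> R x + t."""
        return StructureModel(
            entry_id=self.entry_id,
            chains=[
                (replace(ann), [r.transformed(rotation, translation) for r in residues])
                for ann, residues in self.chains
            ],
        )

    def with_annotations(self, annotations: Iterable[ChainAnnotation]) -> "StructureModel":
        by_id = {a.chain_id: a for a in annotations}
        new_chains = []
        for ann, residues in self.chains:
            new_chains.append((by_id.get(ann.chain_id, replace(ann)), residues))
        return StructureModel(entry_id=self.entry_id, chains=new_chains)

    def renamed_chains(self, renaming: dict[str, str]) -> "StructureModel":
        new_chains = []
        for ann, residues in self.chains:
            new_id = renaming.get(ann.chain_id, ann.chain_id)
            new_ann = replace(ann, chain_id=new_id)
            new_res = [replace(r, chain_id=new_id) for r in residues]
            new_chains.append((new_ann, new_res))
        return StructureModel(entry_id=self.entry_id, chains=new_chains)
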