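"""Reading, writing and annotating macromolecular structures.

mmCIF (PDBx) and PDB parsing is delegated to biotite; this module turns
its flat ``AtomArray`` into the hierarchical :class:`~frapc.model.StructureModel`
the analysis layers consume, applying the package's altloc policy (keep
the highest-occupancy alternate location, ties broken lexicographically)
and keeping only the first model of multi-model files — cryo-EM
depositions are single-model, and single-conformer geometry is what all
downstream calculators assume.

Chain-to-subunit assignment is deliberately an external mapping (TSV or
in-code dict), never inferred from sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from pathlib import Path
from string import ascii_uppercase, ascii_lowercase, digits
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import biotite.structure.io.pdbx as _pdbx

from .errors import StructureFormatError
from .model import AtomSite, ChainAnnotation, ResidueRecord, StructureModel

__all__ = [
    "load_structure",
    "write_structure",
    "select_ligands",
    "annotate_chains",
    "read_annotation_table",
    "write_annotation_table",
]

_EXTRA_FIELDS = ["occupancy", "b_factor"]


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    raise StructureFormatError(
        f"cannot infer format from suffix {suffix!r} of {path}; pass format='mmcif' or 'pdb'"
    )


def _read_atom_array(path: Path, fmt: str) -> tuple[struc.AtomArray, str]:
    """First model as an AtomArray with all altlocs, plus an entry id."""
    try:
        if fmt == "pdb":
            pdb_file = _pdb.PDBFile.read(str(path))
            array = pdb_file.get_structure(
                model=1, altloc="all", extra_fields=_EXTRA_FIELDS
            )
            entry_id = path.stem
        elif fmt == "mmcif":
            cif_file = _pdbx.CIFFile.read(str(path))
            array = _pdbx.get_structure(
                cif_file, model=1, altloc="all", extra_fields=_EXTRA_FIELDS
            )
            entry_id = next(iter(cif_file), path.stem)
        else:
            raise StructureFormatError(f"unknown format {fmt!r}")
    except StructureFormatError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError and friends
        raise StructureFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return array, str(entry_id)


def _resolve_altlocs(residue_atoms: list[AtomSite]) -> list[AtomSite]:
    """Keep one AtomSite per atom name: highest occupancy, ties -> lexicographically
    first altloc identifier."""
    by_name: dict[str, AtomSite] = {}
    order: list[str] = []
    for atom in residue_atoms:
        name = atom.atom_name
        if name not in by_name:
            by_name[name] = atom
            order.append(name)
            continue
        best = by_name[name]
        # strictly higher occupancy wins; ties -> lexicographically first altloc id
        if atom.occupancy > best.occupancy or (
            atom.occupancy == best.occupancy and atom.altloc < best.altloc
        ):
            by_name[name] = atom
    return [by_name[n] for n in order]


def load_structure(
    path: Union[str, Path], format: str = "auto"
) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Only the first model is read; alternate locations are resolved to a
    single conformer; hydrogens are retained if present.  All chains start
    with the default annotation (role ``"other"``) — see
    :func:`annotate_chains`.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    array, entry_id = _read_atom_array(path, fmt)
    if array.array_length() == 0:
        raise StructureFormatError(f"{path}: parsed to an empty structure")

    has_altloc = "altloc_id" in array.get_annotation_categories()
    has_occ = "occupancy" in array.get_annotation_categories()

    chains: list[tuple[ChainAnnotation, list[ResidueRecord]]] = []
    chain_map: dict[str, list[ResidueRecord]] = {}
    residue_map: dict[tuple[str, int, str], list[AtomSite]] = {}
    residue_meta: dict[tuple[str, int, str], bool] = {}
    residue_order: list[tuple[str, int, str]] = []

    for i in range(array.array_length()):
        chain_id = str(array.chain_id[i])
        seq_id = int(array.res_id[i])
        comp_id = str(array.res_name[i])
        key = (chain_id, seq_id, comp_id)
        if key not in residue_map:
            residue_map[key] = []
            residue_meta[key] = not bool(array.hetero[i])
            residue_order.append(key)
        altloc = str(array.altloc_id[i]).strip().rstrip(".") if has_altloc else ""
        occ = float(array.occupancy[i]) if has_occ else 1.0
        residue_map[key].append(
            AtomSite(
                atom_name=str(array.atom_name[i]),
                element=str(array.element[i]),
                coords=np.array(array.coord[i], dtype=float),
                occupancy=min(max(occ, 0.0), 1.0),
                altloc=altloc,
                b_iso=float(array.b_factor[i]) if "b_factor" in array.get_annotation_categories() else 0.0,
            )
        )

    for key in residue_order:
        chain_id, seq_id, comp_id = key
        record = ResidueRecord(
            comp_id=comp_id,
            seq_id=seq_id,
            chain_id=chain_id,
            atoms=_resolve_altlocs(residue_map[key]),
            is_polymer=residue_meta[key],
        )
        chain_map.setdefault(chain_id, []).append(record)

    for chain_id, residues in chain_map.items():
        chains.append((ChainAnnotation(chain_id=chain_id), residues))
    return StructureModel(entry_id=entry_id, chains=chains)


def _to_atom_array(model: StructureModel) -> struc.AtomArray:
    n = model.atom_count()
    array = struc.AtomArray(n)
    array.add_annotation("occupancy", dtype=float)
    array.add_annotation("b_factor", dtype=float)
    i = 0
    for ann, residues in model.chains:
        for res in residues:
            for atom in res.atoms:
                array.chain_id[i] = ann.chain_id
                array.res_id[i] = res.seq_id
                array.res_name[i] = res.comp_id
                array.atom_name[i] = atom.atom_name
                array.element[i] = atom.element
                array.hetero[i] = not res.is_polymer
                array.occupancy[i] = atom.occupancy
                array.b_factor[i] = atom.b_iso
                array.coord[i] = atom.coords
                i += 1
    return array


def _short_chain_ids(chain_ids: Sequence[str]) -> dict[str, str]:
    alphabet = list(ascii_uppercase + ascii_lowercase + digits)
    pool = alphabet + [a + b for a in alphabet for b in alphabet]
    return {cid: pool[i] for i, cid in enumerate(chain_ids)}


def write_structure(
    model: StructureModel,
    path: Union[str, Path],
    format: str = "auto",
    shorten_chains: bool = False,
) -> Optional[dict[str, str]]:
    """Write a model as mmCIF or PDB.

    Chain identifiers longer than the formats allow (4 characters) raise
    unless ``shorten_chains=True``, in which case chains are relabelled
    deterministically and the mapping {original: written} is returned.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    renaming: Optional[dict[str, str]] = None
    limit = 1 if fmt == "pdb" else 4
    if any(len(cid) > limit for cid in model.chain_ids):
        if not shorten_chains:
            raise StructureFormatError(
                f"chain ids {model.chain_ids} exceed the {limit}-character limit of "
                f"{fmt}; pass shorten_chains=True"
            )
        renaming = _short_chain_ids(model.chain_ids)
        model = model.renamed_chains(renaming)
    array = _to_atom_array(model)
    if fmt == "pdb":
        pdb_file = _pdb.PDBFile()
        pdb_file.set_structure(array)
        pdb_file.write(str(path))
    else:
        cif_file = _pdbx.CIFFile()
        _pdbx.set_structure(cif_file, array, data_block=model.entry_id or "model")
        cif_file.write(str(path))
    return renaming


def select_ligands(model: StructureModel, comp_ids: Iterable[str]) -> list[ResidueRecord]:
    """All non-polymer residues whose component id is in ``comp_ids``,
    in deterministic (chain_id, seq_id) order."""
    wanted = set(comp_ids)
    if not wanted:
        raise ValueError("comp_ids must be non-empty")
    hits = [
        res
        for _, res in model.residues()
        if not res.is_polymer and res.comp_id in wanted
    ]
    return sorted(hits, key=lambda r: (r.chain_id, r.seq_id))


def annotate_chains(
    model: StructureModel,
    mapping: Union[Mapping[str, Union[str, ChainAnnotation]], Iterable[ChainAnnotation]],
) -> StructureModel:
    """Attach subunit-role annotations from an external mapping.

    ``mapping`` is either {chain_id: role-string}, {chain_id: ChainAnnotation},
    or an iterable of :class:`ChainAnnotation`.  Chains absent from the
    mapping keep role ``"other"``; mapping entries naming absent chains
    produce a warning, not an error.
    """
    if isinstance(mapping, Mapping):
        annotations = []
        for cid, value in mapping.items():
            if isinstance(value, ChainAnnotation):
                annotations.append(replace(value, chain_id=cid))
            else:
                annotations.append(ChainAnnotation(chain_id=cid, subunit_role=str(value)))
    else:
        annotations = [replace(a) for a in mapping]

    present = set(model.chain_ids)
    missing = sorted({a.chain_id for a in annotations} - present)
    if missing:
        warnings.warn(
            f"annotation mapping names chains absent from {model.entry_id}: {missing}",
            stacklevel=2,
        )
    return model.with_annotations([a for a in annotations if a.chain_id in present])


# ---------------------------------------------------------------------------
# Annotation tables (TSV with columns chain_id, subunit_role, cylinder_index,
# ring_index, rep_domain_ranges; ranges like "90-120;400-450")
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["chain_id", "subunit_role", "cylinder_index", "ring_index", "rep_domain_ranges"]


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    text = (text or "").strip()
    if not text:
        return []
    out = []
    for part in text.split(";"):
        lo, hi = part.split("-")
        out.append((int(lo), int(hi)))
    return out


def read_annotation_table(path: Union[str, Path]) -> list[ChainAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS[:2] if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks required columns {missing}")
    annotations = []
    for _, row in frame.iterrows():
        annotations.append(
            ChainAnnotation(
                chain_id=row["chain_id"],
                subunit_role=row["subunit_role"] or "other",
                cylinder_index=int(row["cylinder_index"]) if row.get("cylinder_index", "") else None,
                ring_index=int(row["ring_index"]) if row.get("ring_index", "") else None,
                rep_domain_ranges=_parse_ranges(row.get("rep_domain_ranges", "")),
            )
        )
    return annotations


def write_annotation_table(
    annotations: Iterable[ChainAnnotation], path: Union[str, Path]
) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "chain_id": a.chain_id,
                "subunit_role": a.subunit_role,
                "cylinder_index": "" if a.cylinder_index is None else a.cylinder_index,
                "ring_index": "" if a.ring_index is None else a.ring_index,
                "rep_domain_ranges": ";".join(f"{lo}-{hi}" for lo, hi in a.rep_domain_ranges),
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
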