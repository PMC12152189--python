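#!/usr/bin/env python
"""Generate the synthetic structure fixtures used by the downstream analyses.

Writes, under --outdir (default results/fixtures):
  * bilin ensembles emulating a far-red APC (alpha sites near-planar, beta
    sites twisted) and a white-light APC (both rings twisted), as mmCIF
    plus a ground-truth table;
  * an antiparallel bicylinder at 30 deg twist with ApcC / ApcE2-REP decoy
    chains and per-subunit bilins, plus its chain-annotation TSV;
  * ApcE2-like and ApcF2-like pocket models around the same chromophore.

All randomness comes from --seed.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from frapc import (
    PartnerSpec,
    SyntheticAssemblySpec,
    SyntheticBilinSpec,
    bilin_model,
    build_bilin,
    build_cylinder_pair,
    build_pocket,
    write_annotation_table,
    write_structure,
)

# Stated world: white-light APC bilins have ring D ~30-40 deg and ring A
# ~20-50 deg off plane; far-red alpha-site bilins are far more planar
# (ring D distorted by 0-30 deg at most, ring A below ~15 deg) while the
# beta sites keep the white-light-like ring D twist.
ENSEMBLES = {
    "wl_apc": dict(roles=["ApcA", "ApcB"], theta_ab=(20.0, 50.0), theta_cd=(30.0, 40.0)),
    "fr_alpha": dict(
        roles=["ApcD2", "ApcD3", "ApcD5", "ApcE2"], theta_ab=(0.0, 15.0),
        theta_cd=(0.0, 30.0),
    ),
    "fr_beta": dict(roles=["ApcB2"], theta_ab=(10.0, 35.0), theta_cd=(30.0, 40.0)),
}
N_PER_ROLE = 6
NOISE_SIGMA = 0.01  # A; light coordinate noise, well below angle resolution


def generate_bilin_ensembles(outdir: Path, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for name, cfg in ENSEMBLES.items():
        ens_dir = outdir / name
        ens_dir.mkdir(parents=True, exist_ok=True)
        for role in cfg["roles"]:
            for i in range(N_PER_ROLE):
                spec = SyntheticBilinSpec(
                    theta_AB=float(rng.uniform(*cfg["theta_ab"])),
                    theta_BC=float(rng.uniform(0.0, 5.0)),
                    theta_CD=float(rng.uniform(*cfg["theta_cd"])),
                    noise_sigma=NOISE_SIGMA,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                residue, truth = build_bilin(spec)
                model = bilin_model(residue, subunit_role=role,
                                    entry_id=f"{name}-{role}-{i}")
                path = ens_dir / f"{role}_{i}.cif"
                write_structure(model, path)
                rows.append({"ensemble": name, "role": role, "path": str(path), **truth})
    return pd.DataFrame(rows)


def generate_bicylinder(outdir: Path, seed: int) -> dict:
    spec = SyntheticAssemblySpec(
        twist_deg=30.0, antiparallel=True, with_bilins=True,
        decoys=("ApcC", "ApcE2-REP"), noise_sigma=0.05, seed=seed,
    )
    model, truth = build_cylinder_pair(spec)
    outdir.mkdir(parents=True, exist_ok=True)
    write_structure(model, outdir / "bicylinder.cif")
    write_annotation_table([ann for ann, _ in model.chains], outdir / "bicylinder_chains.tsv")
    return {
        "path": str(outdir / "bicylinder.cif"),
        "twist_deg": truth["twist_deg"],
        "half_a": truth["half_a"],
        "half_b": truth["half_b"],
        "pairing": truth["pairing"],
    }


def generate_pockets(outdir: Path) -> dict:
    """ApcE2-like vs ApcF2-like pockets: same chromophore, different partners.

    The ApcE2-like pocket has a Trp stacking on ring D, a Thr H-bonding the
    ring-D keto oxygen and one Arg on the ring-C propionate; the ApcF2-like
    pocket lacks the Trp/Thr pair but holds both propionates with arginines.
    """
    residue, _ = build_bilin(SyntheticBilinSpec(theta_AB=5.0, theta_CD=8.0))
    apce2_like = build_pocket(residue, [
        PartnerSpec("TRP", "pi_stack", 3.6, bilin_ring="D", chain_id="P", seq_id=177),
        PartnerSpec("THR", "hbond", 2.9, partner_atom="OG1", bilin_atom="OD",
                    chain_id="P", seq_id=76),
        PartnerSpec("ARG", "salt_bridge", 3.2, partner_atom="NH1", bilin_atom="O1C",
                    chain_id="P", seq_id=120),
    ], entry_id="apce2-like-pocket")
    apcf2_like = build_pocket(residue, [
        PartnerSpec("ARG", "salt_bridge", 3.1, partner_atom="NH1", bilin_atom="O1B",
                    chain_id="Q", seq_id=77),
        PartnerSpec("ARG", "salt_bridge", 3.3, partner_atom="NH2", bilin_atom="O2C",
                    chain_id="Q", seq_id=84),
    ], entry_id="apcf2-like-pocket")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, model in [("apce2_like", apce2_like), ("apcf2_like", apcf2_like)]:
        path = outdir / f"{name}.cif"
        write_structure(model, path)
        paths[name] = str(path)
    return paths


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/fixtures"))
    args = parser.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    truth_frame = generate_bilin_ensembles(args.outdir / "bilins", args.seed)
    truth_frame.to_csv(args.outdir / "bilin_ground_truth.tsv", sep="\t", index=False)
    cyl_info = generate_bicylinder(args.outdir / "bicylinder", args.seed)
    pocket_paths = generate_pockets(args.outdir / "pockets")

    manifest = {
        "seed": args.seed,
        "n_bilins": len(truth_frame),
        "bicylinder": cyl_info,
        "pockets": pocket_paths,
    }
    (args.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote {len(truth_frame)} bilins, 1 bicylinder, 2 pockets -> {args.outdir}")


if __name__ == "__main__":
    main()
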