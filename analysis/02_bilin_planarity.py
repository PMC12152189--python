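#!/usr/bin/env python
"""Bilin planarity profiles across the synthetic ensembles.

Reads the fixture manifest written by 01_generate_fixtures.py, measures the
centered inter-ring plane angles (theta_AB, theta_BC, theta_CD) and the
methine-bridge conformer label of every bilin, compares them against the
generator's ground truth, and writes a tidy per-bilin table.

The summary printed at the end is the synthetic analogue of the planarity
comparison between far-red and white-light APC: alpha-site far-red bilins
are markedly more planar than their white-light counterparts, while the
beta sites keep the white-light-like ring D twist.
"""

import argparse
from pathlib import Path

import pandas as pd

from frapc import load_structure, planarity_profile, profile_to_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    parser.add_argument("--out", type=Path, default=Path("results/bilin_planarity.tsv"))
    args = parser.parse_args()

    truth = pd.read_csv(args.fixtures / "bilin_ground_truth.tsv", sep="\t")
    frames = []
    for _, row in truth.iterrows():
        model = load_structure(row["path"])
        records, skipped = planarity_profile(model)
        assert not skipped, skipped
        frame = profile_to_frame(records)
        frame["ensemble"] = row["ensemble"]
        frame["subunit_role"] = row["role"]
        frame["true_theta_AB"] = row["theta_AB"]
        frame["true_theta_CD"] = row["theta_CD"]
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table["err_AB"] = (table["theta_AB"] - table["true_theta_AB"]).abs()
    table["err_CD"] = (table["theta_CD"] - table["true_theta_CD"]).abs()

    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)

    summary = table.groupby("ensemble")[["theta_AB", "theta_CD", "err_AB", "err_CD"]].mean()
    print(f"wrote {len(table)} bilin records -> {args.out}")
    print("\nmean angles (deg) and recovery error per ensemble:")
    print(summary.round(2).to_string())
    print(
        "\ntheta_BC spread (deg): "
        f"{table['theta_BC'].min():.2f}-{table['theta_BC'].max():.2f} "
        "(small by construction; the B-C bridge barely varies)"
    )


if __name__ == "__main__":
    main()
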