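#!/usr/bin/env python
"""Simulate the phantom cohort and summarize the planted class structure.

Generates the default 52-phantom cohort (24 / 12 / 16 across the three
EF-improvement classes) with the class-dependent uptake-heterogeneity
effect, and a matched null cohort with the effect switched off.  Writes a
per-sample manifest and per-class summaries of simple shell statistics so
the planted signal is visible before any feature engineering.

Usage: python analysis/01_simulate_cohort.py [--seed 7] [--out results/analysis]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from myotex.phantom import CohortConfig, NULL_CLASS_EFFECT, generate_cohort


def summarize(cohort, tag):
    rows = []
    for i, s in enumerate(cohort):
        shell = s.volume.voxels[s.truth_mask.voxels]
        rows.append({
            "sample_id": f"{tag}{i:03d}", "label": s.label,
            "n_shell_voxels": int(s.truth_mask.count()),
            "mean_uptake": shell.mean(), "shell_sd": shell.std(),
            "shell_cov": shell.std() / shell.mean(),
        })
    return pd.DataFrame(rows)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    planted = summarize(generate_cohort(CohortConfig(seed=args.seed)), "P")
    null = summarize(generate_cohort(CohortConfig(
        effect=dict(NULL_CLASS_EFFECT), seed=args.seed + 1)), "N")
    planted.to_csv(out / "cohort_manifest_planted.csv", index=False)
    null.to_csv(out / "cohort_manifest_null.csv", index=False)

    by_class = planted.groupby("label")[["mean_uptake", "shell_sd",
                                         "shell_cov"]].agg(["mean", "std"])
    by_class.to_csv(out / "cohort_class_summary.csv")
    print("planted cohort, per-class shell statistics:")
    print(by_class.round(3))
    print("\nnull cohort shell CoV by class (should be flat):")
    print(null.groupby("label")["shell_cov"].mean().round(4))


if __name__ == "__main__":
    main()
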