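#!/usr/bin/env python
"""Extract the full feature battery for the planted cohort.

Per phantom: the in-house 2D battery (per-pixel Haralick, LAWS, Gabor,
median-image statistics, slice-averaged; 440 features) plus the 269-feature
IBSI-style 3D battery.  Masks come from the automatic segmentation unless
--truth-masks is given.  Writes the features CSV consumed by the
selection / classification / clustering steps.

Usage: python analysis/03_extract_features.py [--seed 7] [--truth-masks]
"""

import argparse
import time
import warnings
from pathlib import Path

from myotex import preprocess
from myotex.phantom import CohortConfig, generate_cohort
from myotex.pipeline import extract_cohort_features, write_feature_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--truth-masks", action="store_true")
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(CohortConfig(seed=args.seed))
    if args.truth_masks:
        masks = [s.truth_mask for s in cohort]
    else:
        masks = [preprocess.segment_lv(s.volume, seed=args.seed)
                 for s in cohort]
    t0 = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = extract_cohort_features(
            [s.volume for s in cohort], masks, [s.label for s in cohort],
            seed=args.seed)
    write_feature_table(table, out / "features.csv")
    print(f"{table.values.shape[0]} samples x {table.values.shape[1]} "
          f"features in {time.time() - t0:.0f}s -> {out / 'features.csv'}")


if __name__ == "__main__":
    main()
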