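#!/usr/bin/env python
"""Rank features with NCA, mRMR and LASSO and screen the NCA top-7.

Reproduces the study's feature-analysis tables on the synthetic cohort: the
7-feature working set per selector, the NCA importances (max-normalized, so
the leading value is 1), and the pairwise Wilcoxon rank-sum p-values of the
selected features across the three class pairs.

Usage: python analysis/04_select_features.py [--features results/analysis/features.csv]
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from myotex import selection
from myotex.pipeline import read_feature_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", default="results/analysis/features.csv")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--k", type=int, default=7)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    table = read_feature_table(args.features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zt = selection.zscore(table)

    results = {
        "nca": selection.nca_rank(zt.values, zt.labels, zt.feature_names,
                                  seed=args.seed, k=args.k),
        "mrmr": selection.mrmr_rank(zt.values, zt.labels, zt.feature_names,
                                    k=args.k, max_rank=args.k),
        "lasso": selection.lasso_select(zt.values, zt.labels,
                                        zt.feature_names, target_k=args.k,
                                        seed=args.seed),
    }
    top = pd.DataFrame({m: r.ranked_names[:args.k]
                        for m, r in results.items()})
    top.to_csv(out / "selected_top7.csv", index=False)
    print("top-7 per selector:")
    print(top)

    nca = results["nca"]
    sel = nca.ranked_names[:args.k]
    wres = selection.pairwise_wilcoxon(zt.subset(sel).values, zt.labels, sel)
    detail = pd.DataFrame({
        "importance": nca.importance[:args.k]}, index=sel).join(wres.p_values)
    detail.to_csv(out / "nca_top7_detail.csv")
    print("\nNCA top-7 importances and pairwise Wilcoxon p-values:")
    print(detail.round(4))


if __name__ == "__main__":
    main()
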