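#!/usr/bin/env python
"""Consensus clustering and correlation structure of the selected features.

Clusters the cohort on the NCA top-7 features: 1000 iterations of
subsampled (80%) average-linkage hierarchical clustering with Pearson
distance, cut at k=3; reports the cluster-class agreement percentages, the
clustergram leaf order and the 7x7 feature correlation matrix.

Usage: python analysis/06_cluster.py [--features results/analysis/features.csv]
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from myotex import clustering, selection
from myotex.pipeline import read_feature_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", default="results/analysis/features.csv")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--k", type=int, default=3)
    ap.add_argument("--iters", type=int, default=1000)
    ap.add_argument("--frac", type=float, default=0.8)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    table = read_feature_table(args.features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zt = selection.zscore(table)
        nca = selection.nca_rank(zt.values, zt.labels, zt.feature_names,
                                 seed=args.seed, k=7)
    sel = nca.ranked_names[:7]
    X = zt.subset(sel).values

    res = clustering.consensus_cluster(X, k=args.k, n_iter=args.iters,
                                       subsample=args.frac, seed=args.seed)
    agr = clustering.cluster_class_agreement(res.assignment, zt.labels)
    np.savetxt(out / "consensus_matrix.csv", res.consensus, delimiter=",",
               fmt="%.4f")
    agr.percentages.to_csv(out / "cluster_class_agreement.csv")
    print("cluster-class agreement (% of each class per matched cluster):")
    print(agr.percentages.round(1))
    print("matched diagonal:", np.round(agr.matched_diagonal, 1))

    corr = clustering.feature_correlation(X, sel)
    corr.to_csv(out / "feature_correlation.csv")
    print("\nfeature correlations (NCA top-7):")
    print(corr.round(2))

    cg = clustering.clustergram(X)
    pd.DataFrame({"sample_order": cg["sample_order"],
                  "label": zt.labels[cg["sample_order"]]}).to_csv(
        out / "clustergram_order.csv", index=False)


if __name__ == "__main__":
    main()
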