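#!/usr/bin/env python
"""Repeated stratified evaluation of the seven classifiers.

For each selector x classifier combination: repetitions of the 2-per-class
stratified holdout (train 46 / validate 6 on the default cohort) with
full-cohort feature selection, reporting macro accuracy / AUC / sensitivity
/ specificity / precision / F-score, the per-class mean +/- sd table for the
best model, and its averaged confusion matrix.

Usage: python analysis/05_classify.py [--reps 25] [--selectors nca mrmr lasso]
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from myotex import evaluation, selection
from myotex.pipeline import read_feature_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", default="results/analysis/features.csv")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--reps", type=int, default=25)
    ap.add_argument("--selectors", nargs="+", default=["nca", "mrmr", "lasso"])
    ap.add_argument("--k", type=int, default=7)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    table = read_feature_table(args.features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zt = selection.zscore(table)
        sel_cols = {}
        for m in args.selectors:
            if m == "nca":
                r = selection.nca_rank(zt.values, zt.labels, zt.feature_names,
                                       seed=args.seed, k=args.k)
            elif m == "mrmr":
                r = selection.mrmr_rank(zt.values, zt.labels,
                                        zt.feature_names, k=args.k,
                                        max_rank=args.k)
            else:
                r = selection.lasso_select(zt.values, zt.labels,
                                           zt.feature_names, target_k=args.k,
                                           seed=args.seed)
            sel_cols[m] = np.array([zt.feature_names.index(n)
                                    for n in r.ranked_names[:args.k]])

    rows, best = [], (None, -1.0)
    for m, cols in sel_cols.items():
        for model in evaluation.MODEL_NAMES:
            res, _ = evaluation.repeated_eval(
                zt, evaluation.ModelSpec(model),
                selector=lambda X, y, s, c=cols: c,
                n_reps=args.reps, seed=args.seed)
            row = {"selector": m, "classifier": model,
                   **{k: round(res.macro_mean[k], 3)
                      for k in evaluation.METRIC_NAMES}}
            rows.append(row)
            if res.macro_mean["auc"] > best[1]:
                best = ((m, model, res), res.macro_mean["auc"])
    df = pd.DataFrame(rows)
    df.to_csv(out / "classifier_metrics.csv", index=False)
    print(df.to_string(index=False))

    (m, model, res) = best[0]
    print(f"\nbest model: {model} on {m} features "
          f"(macro AUC {best[1]:.3f}); per-class mean +/- sd:")
    table6 = res.per_class_mean.round(3).astype(str) + " ± " \
        + res.per_class_sd.round(3).astype(str)
    print(table6.to_string())
    table6.to_csv(out / "best_model_per_class.csv")
    np.savetxt(out / "best_model_confusion.csv", res.confusion, delimiter=",",
               fmt="%.3f")
    print("\naveraged confusion matrix (rows = truth):")
    print(np.round(res.confusion, 2))


if __name__ == "__main__":
    main()
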