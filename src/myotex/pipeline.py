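"""End-to-end orchestration: simulate -> segment -> extract -> select ->
classify -> cluster -> report.

`run_pipeline` executes the stages on a synthetic cohort, persisting every
intermediate as CSV under the output directory, and returns a
:class:`RunReport` whose tables mirror the study's reporting: ranked
features with importances and pairwise Wilcoxon p-values, a per-selector x
per-classifier metric table, per-class mean +/- sd metrics for the best
models, averaged confusion matrices and a consensus-clustering summary.
One master seed deterministically fans out per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, evaluation, preprocess, radiomics3d, selection, texture2d
from .phantom import CohortConfig, generate_cohort


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

def write_feature_table(table: selection.FeatureTable, path) -> None:
    """CSV with header sample_id, label, <features...>; full float precision."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> selection.FeatureTable:
    """Read and validate a feature-table CSV (lossless round trip)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "label"]:
        raise ValueError("feature table must start with sample_id, label columns")
    feature_names = cols[2:]
    dupes = [c for c in set(feature_names) if feature_names.count(c) > 1]
    # pandas mangles duplicate headers to name.1; detect the pattern too
    mangled = [c for c in feature_names
               if "." in c and c.rsplit(".", 1)[0] in feature_names
               and c.rsplit(".", 1)[1].isdigit()]
    if dupes or mangled:
        bad = sorted(set(dupes) | {c.rsplit(".", 1)[0] for c in mangled})
        raise ValueError(f"duplicate feature column(s): {bad}")
    if df["label"].isna().any():
        rows = df.index[df["label"].isna()].tolist()
        raise ValueError(f"missing label in row(s) {rows}")
    vals = df[feature_names]
    numeric = vals.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & ~vals.isna()
    if bad_cells.any().any():
        col = bad_cells.any(axis=0).idxmax()
        row = int(bad_cells[col].idxmax())
        raise ValueError(f"non-numeric cell at row {row}, column {col!r}")
    if numeric.isna().any().any():
        col = numeric.isna().any(axis=0).idxmax()
        raise ValueError(f"missing value(s) in column {col!r}")
    return selection.FeatureTable(
        numeric.to_numpy(float), feature_names,
        df["label"].to_numpy(int), df["sample_id"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Stage toggles and parameters; defaults mirror the study protocol
    (52 phantoms split 24/12/16, 7-feature working set, 100 repetitions of
    the 46/6 stratified holdout, consensus clustering k=3 / 1000 x 80%)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    segment: bool = True                # False -> use phantom truth masks
    extract_2d: bool = True
    extract_3d: bool = True
    selectors: tuple[str, ...] = ("nca", "mrmr", "lasso")
    n_features: int = 7
    models: tuple[str, ...] = evaluation.MODEL_NAMES
    scheme: str = "holdout"
    n_reps: int = 100
    paper_mode: bool = True             # full-cohort selection (study protocol)
    cluster_k: int = 3
    cluster_iters: int = 1000
    cluster_subsample: float = 0.8
    seed: int = 0
    out_dir: str = "results/pipeline"


@dataclass
class RunReport:
    features: selection.FeatureTable
    selection_results: dict[str, selection.SelectionResult]
    wilcoxon: selection.WilcoxonResult
    metrics_table: pd.DataFrame          # selector x classifier macro metrics
    per_class_tables: dict[str, pd.DataFrame]
    confusions: dict[str, np.ndarray]
    consensus_summary: dict
    provenance: dict


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def extract_cohort_features(volumes, masks, labels, extract_2d=True,
                            extract_3d=True, seed: int = 0
                            ) -> selection.FeatureTable:
    """Assemble the feature table: in-house 2D battery (slice-averaged) and
    the 269-feature 3D battery per sample."""
    rows = []
    for i, (vol, mask) in enumerate(zip(volumes, masks)):
        feats: dict[str, float] = {}
        norm = preprocess.normalize_gray_levels(vol)
        if extract_2d:
            feats.update(texture2d.extract_volume_features_2d(norm, mask))
        if extract_3d:
            feats.update(radiomics3d.extract_all(
                norm, mask, spacing=getattr(vol, "spacing", (1, 1, 1)),
                seed=seed + i))
        rows.append(feats)
    names = list(rows[0])
    X = np.array([[r[n] for n in names] for r in rows])
    return selection.FeatureTable(X, names, np.asarray(labels, int))


def make_selector(method: str, k: int = 7):
    """Wrap a ranking method as ``(X, y, seed) -> column indices``."""
    method = method.lower()

    def _fn(X, y, seed):
        if method == "nca":
            res = selection.nca_rank(X, y, seed=seed, k=k)
        elif method == "mrmr":
            res = selection.mrmr_rank(X, y, k=k, max_rank=k)
        elif method == "lasso":
            res = selection.lasso_select(X, y, target_k=k, seed=seed)
        else:
            raise ValueError(f"unknown selector {method!r}")
        top = res.ranked_names[:min(k, len(res.ranked_names))]
        return np.array([int(n[1:]) for n in top])

    return _fn


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order, persist intermediates, and
    return the report; byte-identical under the same config + seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("simulate", "segment", "extract", "select", "classify", "cluster"),
        rng.integers(0, 2 ** 31 - 1, size=6))}

    # simulate
    cohort_cfg = CohortConfig(**{**asdict(config.cohort),
                                 "phantom": config.cohort.phantom,
                                 "seed": stage_seeds["simulate"] % 2 ** 16})
    cohort = generate_cohort(cohort_cfg)
    labels = [s.label for s in cohort]
    volumes = [s.volume for s in cohort]

    # segment
    if config.segment:
        masks = [preprocess.segment_lv(v, seed=stage_seeds["segment"] % 2 ** 16)
                 for v in volumes]
    else:
        masks = [s.truth_mask for s in cohort]

    # extract
    table = extract_cohort_features(
        volumes, masks, labels, config.extract_2d, config.extract_3d,
        seed=stage_seeds["extract"] % 2 ** 16)
    write_feature_table(table, out / "features.csv")
    ztable = selection.zscore(table)

    # select (full-cohort results for the report tables)
    sel_results: dict[str, selection.SelectionResult] = {}
    for method in config.selectors:
        if method == "nca":
            res = selection.nca_rank(ztable.values, ztable.labels,
                                     ztable.feature_names,
                                     seed=stage_seeds["select"] % 2 ** 16,
                                     k=config.n_features)
        elif method == "mrmr":
            res = selection.mrmr_rank(ztable.values, ztable.labels,
                                      ztable.feature_names, k=config.n_features,
                                      max_rank=config.n_features)
        elif method == "lasso":
            res = selection.lasso_select(ztable.values, ztable.labels,
                                         ztable.feature_names,
                                         target_k=config.n_features,
                                         seed=stage_seeds["select"] % 2 ** 16)
        else:
            raise ValueError(f"unknown selector {method!r}")
        sel_results[method] = res
        res.to_frame().head(max(config.n_features, res.k)).to_csv(
            out / f"selected_{method}.csv", index=False)

    primary = config.selectors[0]
    sel_names = selection.select_top_k(
        sel_results[primary], min(config.n_features,
                                  len(sel_results[primary].ranked_names)))
    wres = selection.pairwise_wilcoxon(
        ztable.subset(sel_names).values, ztable.labels, sel_names)
    wres.p_values.to_csv(out / "wilcoxon_selected.csv")

    # classify
    metric_rows = []
    per_class_tables: dict[str, pd.DataFrame] = {}
    confusions: dict[str, np.ndarray] = {}
    for method in config.selectors:
        if config.paper_mode:
            cols = np.array([ztable.feature_names.index(n) for n in
                             selection.select_top_k(
                                 sel_results[method],
                                 min(config.n_features,
                                     len(sel_results[method].ranked_names)))])
            sel_fn = lambda X, y, s, c=cols: c  # noqa: E731
        else:
            sel_fn = make_selector(method, config.n_features)
        for model_name in config.models:
            spec = evaluation.ModelSpec(model_name,
                                        seed=stage_seeds["classify"] % 2 ** 16)
            result, _ = evaluation.repeated_eval(
                ztable, spec, selector=sel_fn, n_reps=config.n_reps,
                scheme=config.scheme,
                seed=stage_seeds["classify"] % 2 ** 16)
            row = {"selector": method, "classifier": model_name}
            row.update({m: result.macro_mean[m] for m in evaluation.METRIC_NAMES})
            metric_rows.append(row)
            key = f"{method}_{model_name}"
            per_class_tables[key] = result.per_class_mean.join(
                result.per_class_sd, rsuffix="_sd")
            confusions[key] = result.confusion
            np.savetxt(out / f"confusion_{key}.csv", result.confusion,
                       delimiter=",")
    metrics_table = pd.DataFrame(metric_rows)
    metrics_table.to_csv(out / "metrics.csv", index=False)
    pd.concat(per_class_tables, names=["model"]).to_csv(out / "per_class.csv")

    # cluster
    Xsel = ztable.subset(sel_names).values
    cres = clustering.consensus_cluster(
        Xsel, k=config.cluster_k, n_iter=config.cluster_iters,
        subsample=config.cluster_subsample,
        seed=stage_seeds["cluster"] % 2 ** 16)
    agreement = clustering.cluster_class_agreement(cres.assignment,
                                                   np.asarray(labels))
    np.savetxt(out / "consensus.csv", cres.consensus, delimiter=",")
    pd.DataFrame({"sample_id": ztable.sample_ids,
                  "cluster": cres.assignment}).to_csv(
        out / "assignment.csv", index=False)
    agreement.percentages.to_csv(out / "agreement.csv")
    corr = clustering.feature_correlation(Xsel, sel_names)
    corr.to_csv(out / "feature_correlation.csv")

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "n_samples": len(labels),
        "n_features": len(table.feature_names),
        "elapsed_s": round(time.time() - t0, 2),
        "versions": _versions(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return RunReport(table, sel_results, wres, metrics_table,
                     per_class_tables, confusions,
                     {"assignment": cres.assignment,
                      "agreement": agreement.percentages,
                      "matched_diagonal": agreement.matched_diagonal},
                     provenance)


def _versions() -> dict[str, str]:
    import scipy
    import skimage
    import sklearn

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "sklearn": sklearn.__version__, "skimage": skimage.__version__,
            "pandas": pd.__version__}
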