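"""Consensus clustering of patients on the selected features, hierarchical
clustergram and feature-correlation analysis.

Consensus clustering follows the subsampling scheme: at each iteration 80%
of the samples are drawn without replacement, hierarchically clustered
(average linkage, distance = 1 - Pearson correlation across the selected
features) and cut at k; the consensus matrix holds, for every sample pair,
the fraction of co-sampled iterations in which the pair landed in the same
cluster.  The final assignment hierarchically clusters 1 - consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class ConsensusResult:
    consensus: np.ndarray       # samples x samples, in [0, 1]
    assignment: np.ndarray      # final cluster id per sample (1..k)
    co_sampled: np.ndarray      # pair co-sampling counts
    k: int


@dataclass
class ClusterClassAgreement:
    percentages: pd.DataFrame   # clusters x classes; class columns sum to 100
    matched_diagonal: np.ndarray  # agreement % of cluster i with class i


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distance between sample rows."""
    corr = np.corrcoef(X)
    corr = np.clip(corr, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    # guard tiny negative rounding
    return squareform(np.clip(d, 0.0, None), checks=False)


def _cut(X: np.ndarray, k: int, metric_condensed: np.ndarray | None = None
         ) -> np.ndarray:
    d = _pearson_distance(X) if metric_condensed is None else metric_condensed
    Z = hierarchy.linkage(d, method="average")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(X_selected, k: int = 3, n_iter: int = 1000,
                      subsample: float = 0.8, seed: int = 0) -> ConsensusResult:
    """Subsampled hierarchical consensus clustering.

    Each of ``n_iter`` iterations clusters ``subsample`` of the samples with
    average linkage on 1 - Pearson distance and cuts at ``k``; consensus =
    co-cluster count / co-sample count per pair.
    """
    X = np.asarray(X_selected, float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if not (0 < subsample <= 1):
        raise ValueError("subsample must lie in (0, 1]")
    if k > n:
        raise ValueError("k cannot exceed the sample count")
    rng = np.random.default_rng(seed)
    m = max(int(round(subsample * n)), k)
    co_cluster = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(n_iter):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        labels = _cut(X[idx], min(k, m))
        onehot = (labels[:, None] == labels[None, :]).astype(float)
        co_cluster[np.ix_(idx, idx)] += onehot
        sampled = np.zeros(n)
        sampled[idx] = 1.0
        co_sampled += np.outer(sampled, sampled)
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, co_cluster / co_sampled, 0.0)
    np.fill_diagonal(consensus, 1.0)
    # final assignment: hierarchical clustering of the consensus dissimilarity
    d = squareform(1.0 - consensus, checks=False)
    Z = hierarchy.linkage(d, method="average")
    assignment = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ConsensusResult(consensus, assignment, co_sampled, k)


def cluster_class_agreement(assignment, labels) -> ClusterClassAgreement:
    """Percentage of each class's members falling in each cluster, with the
    cluster <-> class correspondence fixed by maximum-agreement matching."""
    from scipy.optimize import linear_sum_assignment

    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if len(assignment) != len(labels):
        raise ValueError("assignment and labels must be aligned")
    clusters = np.unique(assignment)
    classes = np.unique(labels)
    pct = np.zeros((len(clusters), len(classes)))
    for i, cl in enumerate(clusters):
        for j, c in enumerate(classes):
            n_class = (labels == c).sum()
            pct[i, j] = 100.0 * ((assignment == cl) & (labels == c)).sum() / n_class
    # reorder clusters so cluster i best matches class i
    ncl, ncls = pct.shape
    if ncl == ncls:
        row, col = linear_sum_assignment(-pct)
        order = row[np.argsort(col)]
        pct = pct[order]
        clusters = clusters[order]
    df = pd.DataFrame(pct, index=[f"cluster{i+1}" for i in range(len(clusters))],
                      columns=[f"class{int(c)}" for c in classes])
    diag = np.diag(pct) if ncl == ncls else np.zeros(0)
    return ClusterClassAgreement(df, diag)


def clustergram(X_selected) -> dict:
    """Hierarchical clustergram: average-linkage trees over samples and over
    features plus the induced reorder permutations (rendering optional)."""
    X = np.asarray(X_selected, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    from scipy.spatial.distance import pdist

    Zs = hierarchy.linkage(pdist(X), method="average")
    Zf = hierarchy.linkage(pdist(X.T), method="average") if X.shape[1] > 1 \
        else None
    sample_order = hierarchy.leaves_list(Zs)
    feature_order = hierarchy.leaves_list(Zf) if Zf is not None \
        else np.array([0])
    return {
        "sample_linkage": Zs, "feature_linkage": Zf,
        "sample_order": sample_order, "feature_order": feature_order,
        "matrix": X[np.ix_(sample_order, feature_order)],
    }


def feature_correlation(X_selected, feature_names=None) -> pd.DataFrame:
    """Pairwise Pearson correlation of the selected features."""
    X = np.asarray(X_selected, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if (X.std(axis=0) == 0).any():
        raise ValueError("zero-variance feature in correlation analysis")
    corr = np.corrcoef(X.T)
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(corr, index=names, columns=names)
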