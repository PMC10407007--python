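"""Feature standardization, NCA / mRMR / LASSO ranking and Wilcoxon screening.

The three selectors mirror the study design: neighbourhood component
analysis learns per-feature weights by maximizing the expected leave-one-out
stochastic-neighbour classification accuracy (diagonal NCA, fscnca-style);
mRMR greedily maximizes mutual information with the label minus mean mutual
information with the already-selected set (MID variant, equal-frequency
binning); LASSO searches the L1 path of a multinomial logistic regression
for the penalty whose active set has the requested size.  Pairwise
two-sided Wilcoxon rank-sum tests screen each feature across the three
class pairs (C1C2, C1C3, C2C3).

By default selection is meant to run inside each training split of the
evaluation loop; full-cohort selection (as typically done in small-cohort
radiomics studies) is available via the evaluation module's ``paper_mode``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FeatureTable:
    """samples x named-features matrix with 3-level class labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (samples x features)")
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError("feature name count does not match matrix width")
        if len(set(self.feature_names)) != d:
            dupes = [f for f in self.feature_names
                     if self.feature_names.count(f) > 1]
            raise ValueError(f"duplicated feature names: {sorted(set(dupes))}")
        if len(self.labels) != n:
            raise ValueError("label count does not match sample count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(n)]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def subset(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.values[:, idx], list(names), self.labels,
                            list(self.sample_ids))


@dataclass
class SelectionResult:
    method: str
    ranked_names: list[str]
    importance: np.ndarray  # aligned with ranked_names, descending
    k: int
    raw_weights: np.ndarray | None = None  # un-normalized, aligned too

    @property
    def selected(self) -> list[str]:
        return self.ranked_names[: self.k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.ranked_names,
            "importance": self.importance,
            "rank": np.arange(1, len(self.ranked_names) + 1),
        })


@dataclass
class WilcoxonResult:
    feature_names: list[str]
    p_values: pd.DataFrame  # columns C1C2, C1C3, C2C3


def zscore(table: FeatureTable) -> FeatureTable:
    """Standardize every feature to mean 0, population sd 1.

    Zero-variance features are dropped with a warning so downstream
    selectors never divide by zero.
    """
    if table.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    X = table.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
                      stacklevel=2)
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    names = [n for n, k in zip(table.feature_names, keep) if k]
    return FeatureTable(Z, names, table.labels, list(table.sample_ids))


# ---------------------------------------------------------------------------
# NCA (diagonal, per-feature weights)
# ---------------------------------------------------------------------------

NCA_LAMBDA_GRID = (0.25, 0.5, 1.0, 2.0)


def _nca_fit(X, y, lam: float, seed: int, n_iter: int) -> np.ndarray:
    """L-BFGS on the stochastic leave-one-out NCA objective with weighted
    L1 distances d_ij = sum_r w_r^2 |x_ir - x_jr|; returns the weights."""
    from scipy.optimize import minimize

    n, d = X.shape
    absdiff = np.abs(X[:, None, :] - X[None, :, :])  # (n, n, d)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    eye = np.eye(n, dtype=bool)

    def neg_obj_grad(w):
        w2 = w ** 2
        dist = absdiff @ w2
        dist[eye] = np.inf
        dmin = np.min(dist, axis=1, keepdims=True)
        ker = np.exp(-(dist - dmin))
        ker[eye] = 0.0
        denom = ker.sum(axis=1, keepdims=True)
        P = ker / np.where(denom > 0, denom, 1.0)
        p_i = (P * same).sum(axis=1)
        obj = p_i.sum() - lam * w2.sum()
        # dF/dw2_r = sum_i [p_i sum_j P_ij |d_ijr| - sum_{j in class} P_ij |d_ijr|]
        W1 = P * p_i[:, None]
        W2 = P * same
        grad_w2 = np.einsum("ij,ijr->r", W1 - W2, absdiff) - lam
        return -obj, -(2.0 * w * grad_w2)

    rng = np.random.default_rng(seed)
    w0 = 1.0 + 0.05 * rng.standard_normal(d)
    res = minimize(neg_obj_grad, w0, jac=True, method="L-BFGS-B",
                   options={"maxiter": n_iter})
    return res.x


def _nca_holdout_score(Xtr, ytr, Xva, yva, w2: np.ndarray) -> float:
    """Expected stochastic-neighbour accuracy of validation points against
    the training set under the learned weighted distance."""
    dist = np.abs(Xva[:, None, :] - Xtr[None, :, :]) @ w2
    dmin = dist.min(axis=1, keepdims=True)
    ker = np.exp(-(dist - dmin))
    P = ker / ker.sum(axis=1, keepdims=True)
    same = (yva[:, None] == ytr[None, :]).astype(float)
    return float((P * same).sum(axis=1).mean())


def nca_rank(X, y, feature_names=None, regularization: float | None = None,
             seed: int = 0, n_iter: int = 100, k: int = 7) -> SelectionResult:
    """Per-feature NCA weights (diagonal NCA, fscnca-style).

    Importance = w^2 / max(w^2), so the top feature scores exactly 1.  When
    ``regularization`` is None the L2 penalty is picked from a small grid by
    a stratified 70/30 holdout on the stochastic-neighbour accuracy, with
    ties broken toward the stronger penalty (noise weights then collapse on
    label-independent data).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    n, d = X.shape
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(d)]

    if regularization is None:
        rng = np.random.default_rng(seed)
        val_idx = np.concatenate([
            rng.choice(np.flatnonzero(y == c),
                       max(1, int(round(0.3 * (y == c).sum()))), replace=False)
            for c in np.unique(y)
        ])
        tr_idx = np.setdiff1d(np.arange(n), val_idx)
        best_lam, best_score = NCA_LAMBDA_GRID[0], -np.inf
        for lam in NCA_LAMBDA_GRID:
            w = _nca_fit(X[tr_idx], y[tr_idx], lam, seed, n_iter)
            score = _nca_holdout_score(X[tr_idx], y[tr_idx],
                                       X[val_idx], y[val_idx], w ** 2)
            if score >= best_score - 1e-6:  # ties -> larger lambda
                best_lam, best_score = lam, max(score, best_score)
        lam = best_lam
    else:
        lam = float(regularization)

    w2 = _nca_fit(X, y, lam, seed, n_iter) ** 2
    imp = w2 / w2.max() if w2.max() > 0 else w2
    order = np.lexsort((names, -imp))
    return SelectionResult("NCA", [names[i] for i in order], imp[order],
                           min(k, d), raw_weights=w2[order])


# ---------------------------------------------------------------------------
# mRMR (MID variant)
# ---------------------------------------------------------------------------

def _discretize_ef(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning to integer codes."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    from sklearn.metrics import mutual_info_score

    return float(mutual_info_score(a, b))


def mrmr_rank(X, y, feature_names=None, n_bins: int = 8, k: int = 7,
              max_rank: int | None = None) -> SelectionResult:
    """Greedy forward mRMR: maximize MI(feature; label) minus mean MI with the
    already-selected features (MID difference scheme).  Deterministic given
    the binning; ranks the full feature set in greedy order unless
    ``max_rank`` truncates the greedy stage (the tail is then ordered by
    plain relevance, which only matters beyond the selected set)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(d)]
    disc = np.column_stack([_discretize_ef(X[:, j], n_bins) for j in range(d)])
    relevance = np.array([_mi(disc[:, j], y) for j in range(d)])

    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(d)
    remaining = set(range(d))
    limit = d if max_rank is None else min(max_rank, d)
    while remaining and len(selected) < limit:
        if not selected:
            crit = relevance.copy()
        else:
            crit = relevance - red_sum / len(selected)
        crit_masked = np.full(d, -np.inf)
        rem = sorted(remaining)
        crit_masked[rem] = crit[rem]
        # stable tie-break by name order
        best = min(rem, key=lambda j: (-crit_masked[j], names[j]))
        selected.append(best)
        scores.append(float(crit_masked[best]))
        remaining.discard(best)
        if remaining and len(selected) < limit:
            for j in remaining:
                red_sum[j] += _mi(disc[:, j], disc[:, best])
    if remaining:  # truncated greedy: order the tail by relevance
        tail = sorted(remaining, key=lambda j: (-relevance[j], names[j]))
        selected.extend(tail)
        scores.extend(relevance[j] for j in tail)
    return SelectionResult("MRMR", [names[i] for i in selected],
                           np.array(scores), min(k, d))


# ---------------------------------------------------------------------------
# LASSO (multinomial logistic L1 path)
# ---------------------------------------------------------------------------

def lasso_select(X, y, feature_names=None, target_k: int = 7, seed: int = 0,
                 max_bisect: int = 30) -> SelectionResult:
    """Bisect the L1 penalty of a multinomial logistic regression for the
    largest penalty whose active set (features with any nonzero class
    coefficient) has exactly ``target_k`` members; if no penalty achieves
    that size, the nearest achievable set is returned with a warning."""
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(d)]

    def fit(C: float):
        clf = LogisticRegression(penalty="l1", C=C, solver="saga",
                                 max_iter=5000, tol=1e-5, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        imp = np.abs(clf.coef_).max(axis=0)
        return imp, int((imp > 1e-8).sum())

    c_lo, c_hi = 1e-4, 1e4
    imp_lo, k_lo = fit(c_lo)
    imp_hi, k_hi = fit(c_hi)
    best_imp, best_k, best_c = imp_hi, k_hi, c_hi
    if k_lo >= target_k:
        best_imp, best_k = imp_lo, k_lo
    else:
        for _ in range(max_bisect):
            c_mid = np.sqrt(c_lo * c_hi)
            imp_mid, k_mid = fit(c_mid)
            if abs(k_mid - target_k) <= abs(best_k - target_k):
                best_imp, best_k, best_c = imp_mid, k_mid, c_mid
            if k_mid < target_k:
                c_lo = c_mid
            else:
                c_hi = c_mid  # prefer smaller lambda (larger C) on ties
            if c_hi / c_lo < 1.05 and best_k == target_k:
                break
    if best_k != target_k:
        warnings.warn(f"no penalty reaches exactly {target_k} active features; "
                      f"returning {best_k}", stacklevel=2)
    order = np.lexsort((names, -best_imp))
    return SelectionResult("LASSO", [names[i] for i in order], best_imp[order],
                           max(best_k, 1))


# ---------------------------------------------------------------------------
# Top-k and Wilcoxon screening
# ---------------------------------------------------------------------------

def select_top_k(result: SelectionResult, k: int | None = None) -> list[str]:
    """Top-k ranked feature names (default k = result.k, itself defaulting to
    the 7-feature working set); ties were already broken by name order."""
    k = result.k if k is None else k
    if not (1 <= k <= len(result.ranked_names)):
        raise ValueError(f"k={k} out of range 1..{len(result.ranked_names)}")
    return result.ranked_names[:k]


def ranksum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when both groups have <= 10
    untied observations, else normal approximation with continuity and tie
    correction."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def pairwise_wilcoxon(X, y, feature_names=None) -> WilcoxonResult:
    """Per-feature two-sided rank-sum p-values for the class pairs C1C2,
    C1C3 and C2C3."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = (1, 2, 3)
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    d = X.shape[1]
    names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(d)]
    pairs = {"C1C2": (1, 2), "C1C3": (1, 3), "C2C3": (2, 3)}
    table = {
        pname: [ranksum_p(X[y == c1, j], X[y == c2, j]) for j in range(d)]
        for pname, (c1, c2) in pairs.items()
    }
    return WilcoxonResult(names, pd.DataFrame(table, index=names))
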