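"""Seven-classifier roster, repeated stratified evaluation and metric reports.

The roster reproduces the study's MATLAB presets with explicit
hyperparameters: cosine KNN (10-NN, cosine distance), fine KNN (1-NN),
subspace KNN (30 x 1-NN on random half-dimensional feature subspaces),
cross-entropy decision tree, RUSBoosted shallow trees, cubic-kernel SVM and
a 100-tree random forest.

Two repetition schemes are provided because the study describes both:
``holdout`` draws a stratified validation set of 2 patients per class (6 of
52) per repetition and trains on the remaining 46, optionally bootstrapping
the training portion; ``full-coverage`` stratified-partitions all samples
into folds so every sample is predicted exactly once per repetition (the
averaged confusion matrix rows then sum to the class sizes).  Metrics are
one-vs-rest per class (accuracy, AUC, sensitivity, specificity, precision,
F-score) averaged over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import ranksum_p

MODEL_NAMES = (
    "cosine_knn", "fine_knn", "subspace_knn", "crossentropy_tree",
    "rusboost_trees", "cubic_svm", "random_forest",
)

METRIC_NAMES = ("accuracy", "auc", "sensitivity", "specificity",
                "precision", "fscore")


@dataclass
class ModelSpec:
    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; "
                             f"roster: {MODEL_NAMES}")


class _RUSBoost:
    """SAMME-style boosting with per-round random undersampling to the
    minority class; shallow trees, learning rate 0.1."""

    def __init__(self, n_rounds=30, max_depth=3, learning_rate=0.1, seed=0):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X, y):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(self.seed)
        self.classes_ = np.unique(y)
        K = len(self.classes_)
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        n_min = min(np.bincount(np.searchsorted(self.classes_, y)))
        for r in range(self.n_rounds):
            idx = []
            for c in self.classes_:
                members = np.flatnonzero(y == c)
                p = w[members] / w[members].sum()
                take = rng.choice(members, size=n_min, replace=True, p=p)
                idx.extend(take)
            idx = np.array(idx)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, criterion="log_loss",
                random_state=int(rng.integers(2 ** 31 - 1)))
            tree.fit(X[idx], y[idx])
            pred = tree.predict(X)
            err = w[pred != y].sum() / w.sum()
            if err >= 1 - 1.0 / K:
                continue
            err = max(err, 1e-10)
            alpha = self.learning_rate * (np.log((1 - err) / err) + np.log(K - 1))
            if alpha <= 0:
                continue
            w *= np.exp(alpha * (pred != y))
            w /= w.sum()
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
        if not self.estimators_:  # degenerate: fall back to a single tree
            tree = DecisionTreeClassifier(max_depth=self.max_depth,
                                          random_state=self.seed)
            tree.fit(X, y)
            self.estimators_, self.alphas_ = [tree], [1.0]
        return self

    def predict_proba(self, X):
        K = len(self.classes_)
        votes = np.zeros((len(X), K))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            for k, c in enumerate(self.classes_):
                votes[pred == c, k] += alpha
        total = votes.sum(axis=1, keepdims=True)
        return votes / np.where(total > 0, total, 1.0)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class _ScoredSVC:
    """Cubic-kernel one-vs-one SVM with summed pairwise decision values as
    per-class scores (normalized to a probability-like simplex)."""

    def __init__(self, seed=0, C=1.0, degree=3):
        from sklearn.svm import SVC

        self._svc = SVC(kernel="poly", degree=degree, C=C,
                        decision_function_shape="ovr", random_state=seed)

    def fit(self, X, y):
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        return self

    def predict(self, X):
        return self._svc.predict(X)

    def predict_proba(self, X):
        d = self._svc.decision_function(X)
        if d.ndim == 1:
            d = np.column_stack([-d, d])
        e = np.exp(d - d.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


def build_classifier(spec: ModelSpec):
    """Instantiate one roster classifier with train/score interface
    (sklearn estimator exposing fit / predict / predict_proba)."""
    from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.tree import DecisionTreeClassifier

    p = spec.params
    if spec.name == "cosine_knn":
        return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 10),
                                    metric="cosine")
    if spec.name == "fine_knn":
        return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 1))
    if spec.name == "subspace_knn":
        return BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=p.get("n_estimators", 30),
            max_features=p.get("max_features", 0.5),
            bootstrap=False, random_state=spec.seed)
    if spec.name == "crossentropy_tree":
        return DecisionTreeClassifier(criterion="log_loss",
                                      min_samples_leaf=1,
                                      random_state=spec.seed)
    if spec.name == "rusboost_trees":
        return _RUSBoost(n_rounds=p.get("n_rounds", 30),
                         max_depth=p.get("max_depth", 3),
                         learning_rate=p.get("learning_rate", 0.1),
                         seed=spec.seed)
    if spec.name == "cubic_svm":
        return _ScoredSVC(seed=spec.seed, C=p.get("C", 1.0),
                          degree=p.get("degree", 3))
    if spec.name == "random_forest":
        return RandomForestClassifier(n_estimators=p.get("n_estimators", 100),
                                      max_features="sqrt",
                                      random_state=spec.seed)
    raise ValueError(spec.name)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_curve(scores, labels):
    """ROC points and trapezoid AUC for binary labels and real scores.

    Ties are handled by grouping equal scores into one threshold step; the
    AUC then equals the rank-statistic (Mann-Whitney) value.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    tps = np.cumsum(lab)
    fps = np.cumsum(~lab)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def per_class_metrics(confusion, scores=None, y_true=None,
                      classes=(1, 2, 3)) -> pd.DataFrame:
    """One-vs-rest metrics per class from a confusion matrix (rows = truth),
    with AUC from per-class scores when provided.

    Undefined ratios (zero denominators) report 0 and set the ``flagged``
    column.
    """
    C = np.asarray(confusion, float)
    K = C.shape[0]
    total = C.sum()
    rows = []
    for k in range(K):
        tp = C[k, k]
        fn = C[k].sum() - tp
        fp = C[:, k].sum() - tp
        tn = total - tp - fn - fp
        flagged = False

        def ratio(num, den):
            nonlocal flagged
            if den <= 0:
                flagged = True
                return 0.0
            return num / den

        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        prec = ratio(tp, tp + fp)
        f1 = ratio(2 * prec * sens, prec + sens)
        acc = ratio(tp + tn, total)
        auc = np.nan
        if scores is not None and y_true is not None:
            y_bin = np.asarray(y_true) == classes[k]
            if 0 < y_bin.sum() < len(y_bin):
                auc = roc_curve(np.asarray(scores)[:, k], y_bin)[2]
        rows.append({"class": classes[k], "accuracy": acc, "auc": auc,
                     "sensitivity": sens, "specificity": spec,
                     "precision": prec, "fscore": f1, "flagged": flagged})
    return pd.DataFrame(rows).set_index("class")


# ---------------------------------------------------------------------------
# Repeated evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    per_class_mean: pd.DataFrame
    per_class_sd: pd.DataFrame
    macro_mean: pd.Series
    confusion: np.ndarray  # averaged, real-valued cells
    n_reps: int
    scheme: str
    train_size: int
    val_size: int


@dataclass
class MetricDistribution:
    metric: str
    values: np.ndarray  # one macro value per repetition


def repeated_eval(table, spec: ModelSpec, selector=None, n_reps: int = 100,
                  scheme: str = "holdout", seed: int = 0,
                  n_val_per_class: int = 2, bootstrap: bool = True,
                  n_folds: int = 10, paper_mode: bool = False
                  ) -> tuple[EvaluationResult, dict[str, MetricDistribution]]:
    """Repeat a stratified train/validate cycle ``n_reps`` times.

    ``selector`` is an optional callable ``(X_train, y_train, seed) ->
    feature index array`` applied inside each training split; with
    ``paper_mode`` it is applied once to the full table before the loop
    (full-cohort selection, as small-cohort studies typically do).
    """
    X_all = np.asarray(table.values, float)
    y_all = np.asarray(table.labels, int)
    classes = np.unique(y_all)
    counts = {c: int((y_all == c).sum()) for c in classes}
    if scheme == "holdout" and any(v <= n_val_per_class for v in counts.values()):
        raise ValueError("a class is too small for the per-class holdout")
    rng_master = np.random.default_rng(seed)
    rep_seeds = rng_master.integers(0, 2 ** 31 - 1, size=n_reps)

    if paper_mode and selector is not None:
        global_idx = np.asarray(selector(X_all, y_all, int(rep_seeds[0] % 2**16)))

    conf_sum = np.zeros((len(classes), len(classes)))
    metric_rows_mean, metric_rows_sd = [], []
    per_rep_class, macro_dist = [], {m: [] for m in METRIC_NAMES}
    train_size = val_size = 0

    for rep in range(n_reps):
        rng = np.random.default_rng(int(rep_seeds[rep]))
        if scheme == "holdout":
            val_idx = np.concatenate([
                rng.choice(np.flatnonzero(y_all == c), n_val_per_class,
                           replace=False)
                for c in classes
            ])
            train_idx = np.setdiff1d(np.arange(len(y_all)), val_idx)
            if bootstrap:
                train_idx = np.concatenate([
                    rng.choice(train_idx[y_all[train_idx] == c],
                               size=(y_all[train_idx] == c).sum(), replace=True)
                    for c in classes
                ])
            splits = [(train_idx, val_idx)]
        elif scheme == "full-coverage":
            from sklearn.model_selection import StratifiedKFold

            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=int(rep_seeds[rep] % 2**31))
            splits = list(skf.split(X_all, y_all))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")

        y_true_rep, y_pred_rep, scores_rep = [], [], []
        for train_idx, val_idx in splits:
            train_size, val_size = len(train_idx), len(val_idx)
            Xtr, ytr = X_all[train_idx], y_all[train_idx]
            Xva = X_all[val_idx]
            if paper_mode and selector is not None:
                cols = global_idx
            elif selector is not None:
                cols = np.asarray(selector(Xtr, ytr, int(rep_seeds[rep] % 2**16)))
            else:
                cols = np.arange(X_all.shape[1])
            model = build_classifier(
                ModelSpec(spec.name, dict(spec.params),
                          seed=int(rep_seeds[rep] % 2**31)))
            model.fit(Xtr[:, cols], ytr)
            pred = model.predict(Xva[:, cols])
            if hasattr(model, "predict_proba"):
                proba = model.predict_proba(Xva[:, cols])
                proba = _expand_proba(proba, model.classes_, classes)
            else:
                proba = np.zeros((len(val_idx), len(classes)))
                for i, p_ in enumerate(pred):
                    proba[i, list(classes).index(p_)] = 1.0
            y_true_rep.extend(y_all[val_idx])
            y_pred_rep.extend(pred)
            scores_rep.append(proba)

        y_true_rep = np.array(y_true_rep)
        y_pred_rep = np.array(y_pred_rep)
        scores_rep = np.vstack(scores_rep)
        conf = _confusion(y_true_rep, y_pred_rep, classes)
        conf_sum += conf
        dfm = per_class_metrics(conf, scores_rep, y_true_rep, tuple(classes))
        dfm["auc"] = dfm["auc"].fillna(0.0)
        per_rep_class.append(dfm[list(METRIC_NAMES)])
        for m in METRIC_NAMES:
            macro_dist[m].append(float(dfm[m].mean()))

    stack = np.stack([df.values for df in per_rep_class])  # (reps, K, metrics)
    mean_df = pd.DataFrame(stack.mean(axis=0), index=per_rep_class[0].index,
                           columns=METRIC_NAMES)
    sd_df = pd.DataFrame(stack.std(axis=0), index=per_rep_class[0].index,
                         columns=METRIC_NAMES)
    result = EvaluationResult(
        per_class_mean=mean_df, per_class_sd=sd_df,
        macro_mean=mean_df.mean(axis=0),
        confusion=conf_sum / n_reps, n_reps=n_reps, scheme=scheme,
        train_size=train_size, val_size=val_size,
    )
    dists = {m: MetricDistribution(m, np.array(v)) for m, v in macro_dist.items()}
    return result, dists


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    K = len(classes)
    lookup = {c: i for i, c in enumerate(classes)}
    C = np.zeros((K, K))
    for t, p in zip(y_true, y_pred):
        C[lookup[t], lookup.get(p, lookup[t])] += 1
    return C


def _expand_proba(proba, model_classes, all_classes) -> np.ndarray:
    out = np.zeros((proba.shape[0], len(all_classes)))
    for j, c in enumerate(model_classes):
        out[:, list(all_classes).index(c)] = proba[:, j]
    return out


def compare_distributions(a: MetricDistribution, b: MetricDistribution) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two repetition distributions
    (shared implementation with the feature-screening tests); significance
    is conventionally read at 0.05."""
    if len(a.values) == 0 or len(b.values) == 0:
        raise ValueError("empty metric distribution")
    if len(a.values) != len(b.values):
        raise ValueError("distributions must have equal length")
    if np.array_equal(a.values, b.values):
        return 1.0
    return ranksum_p(a.values, b.values)
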