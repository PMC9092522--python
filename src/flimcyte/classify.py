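"""Reprogramming-status classification from single-cell feature tables.

Random-forest (default), logistic-regression, k-nearest-neighbor and
naive-Bayes classifiers behind one interface, evaluated with repeated
k-fold cross-validation (15 folds, fold assignments re-drawn before each
repeat), one-vs-rest ROC analysis, gain-ratio feature weighting, and the
accuracy-versus-parameter-count curve obtained by adding features in
descending gain-ratio order.

Gain ratio of a feature A for class variable C is

    GR(A) = [H(C) - H(C|A)] / H(A)

with entropies in bits and continuous features discretized into
equal-frequency bins; GR is defined as 0 when H(A) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import METABOLIC_COLUMNS, NUCLEAR_COLUMNS

__all__ = [
    "ALL_PARAMETERS",
    "FAD_LIFETIME_PRESET",
    "CVPlan",
    "ForestConfig",
    "ClassifierReport",
    "make_cv_plan",
    "gain_ratio",
    "rank_by_gain_ratio",
    "train_forest",
    "roc_ovr",
    "accuracy_vs_k",
]

ALL_PARAMETERS = list(METABOLIC_COLUMNS) + list(NUCLEAR_COLUMNS)

#: FAD-channel-only lifetime preset: classification from the single FAD
#: acquisition, trading a small accuracy loss for halved imaging time.
FAD_LIFETIME_PRESET = ["fad_tau_m", "fad_tau1", "fad_tau2", "fad_alpha1"]


@dataclass
class CVPlan:
    """Repeated k-fold assignments: ``folds[r][i]`` is the test fold of
    cell ``i`` in repeat ``r``.  Folds partition the cells; sizes differ
    by at most one."""

    n_folds: int
    n_repeats: int
    seed: int
    folds: np.ndarray  # (n_repeats, n_cells) int

    @property
    def n_cells(self) -> int:
        return self.folds.shape[1]

    def fold_sizes(self, repeat: int = 0) -> np.ndarray:
        return np.bincount(self.folds[repeat], minlength=self.n_folds)


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings: 100 trees, sqrt(p) features per split,
    unlimited depth."""

    n_trees: int = 100
    max_features: str | float = "sqrt"
    max_depth: int | None = None


def make_cv_plan(
    n_cells: int,
    n_folds: int = 15,
    n_repeats: int = 100,
    seed: int | None = None,
    labels: np.ndarray | None = None,
) -> CVPlan:
    """Randomly partition cells into folds, re-drawn for every repeat.

    Unlabeled: a shuffled split into ``n_folds`` contiguous blocks of
    size ceil(n/k) or floor(n/k).  With ``labels``, the assignment is
    stratified: within each class, shuffled cells are dealt one at a
    time to the currently smallest fold, which keeps overall fold sizes
    within one of each other while representing every class in every
    fold where counts permit.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n_cells:
        raise ValueError("n_folds cannot exceed n_cells")
    rng = np.random.default_rng(seed)
    folds = np.empty((n_repeats, n_cells), dtype=np.int64)
    for r in range(n_repeats):
        if labels is None:
            perm = rng.permutation(n_cells)
            sizes = np.full(n_folds, n_cells // n_folds)
            sizes[: n_cells % n_folds] += 1
            bounds = np.concatenate([[0], np.cumsum(sizes)])
            for f in range(n_folds):
                folds[r, perm[bounds[f]:bounds[f + 1]]] = f
        else:
            counts = np.zeros(n_folds, dtype=np.int64)
            assign = np.empty(n_cells, dtype=np.int64)
            for cls in pd.unique(np.asarray(labels)):
                idx = np.nonzero(np.asarray(labels) == cls)[0]
                idx = rng.permutation(idx)
                for i in idx:
                    f = int(np.argmin(counts))
                    assign[i] = f
                    counts[f] += 1
            folds[r] = assign
    return CVPlan(n_folds=n_folds, n_repeats=n_repeats,
                  seed=seed if seed is not None else -1, folds=folds)


# ---------------------------------------------------------------------------
# gain ratio


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def discretize_equal_frequency(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning; already-discrete features (fewer unique
    values than bins) are left as their own categories."""
    values = np.asarray(values)
    uniq = np.unique(values)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, values)
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), values, side="right")


def gain_ratio(
    values: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
    discretizer=None,
) -> float:
    """Gain ratio of one feature: information gain over attribute entropy.

    ``discretizer`` maps continuous values to categories (default:
    equal-frequency bins).  Returns 0 when the discretized attribute is
    constant (H(A) = 0).
    """
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("gain ratio requires >= 2 classes")
    if discretizer is None:
        a = discretize_equal_frequency(np.asarray(values), n_bins)
    else:
        a = np.asarray(discretizer(np.asarray(values)))
    cats, a = np.unique(a, return_inverse=True)
    h_c = _entropy_bits(np.bincount(y))
    h_a = _entropy_bits(np.bincount(a))
    if h_a == 0.0:
        return 0.0
    h_c_given_a = 0.0
    n = y.size
    for cat in range(cats.size):
        sel = a == cat
        h_c_given_a += sel.sum() / n * _entropy_bits(np.bincount(y[sel]))
    return (h_c - h_c_given_a) / h_a


def rank_by_gain_ratio(
    records: pd.DataFrame,
    params: list[str] | None = None,
    label_col: str = "cell_class",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Gain ratio per parameter, sorted descending."""
    params = params or [p for p in ALL_PARAMETERS if p in records.columns]
    if not params:
        raise ValueError("no rankable parameter columns in records")
    y = records[label_col].to_numpy()
    weights = {p: gain_ratio(records[p].to_numpy(), y, n_bins=n_bins)
               for p in params}
    out = pd.DataFrame({"parameter": list(weights), "gain_ratio":
                        list(weights.values())})
    return out.sort_values("gain_ratio", ascending=False,
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROC


def roc_ovr(scores: np.ndarray, positive: np.ndarray) -> dict:
    """One-vs-rest ROC curve and AUC for one class.

    ``scores`` are the class scores, ``positive`` the boolean class
    membership.  The curve sweeps the unique score thresholds; the AUC
    equals the tie-corrected Mann-Whitney statistic (rank-average over
    ties), i.e. the trapezoidal area under the stepwise curve.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if positive.all() or not positive.any():
        raise ValueError("need both positive and negative examples")
    fpr, tpr, thr = roc_curve(positive, scores)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr,
            "auc": float(np.trapezoid(tpr, fpr))}


# ---------------------------------------------------------------------------
# classifiers


def _build_estimator(method: str, cfg: ForestConfig, seed: int):
    if method == "random_forest":
        return RandomForestClassifier(
            n_estimators=cfg.n_trees, max_features=cfg.max_features,
            max_depth=cfg.max_depth, random_state=seed)
    if method == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000))
    if method == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if method == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ClassifierReport:
    """Cross-validated classification summary averaged over repeats."""

    method: str
    params: list[str]
    classes: list[str]
    accuracy: float
    accuracy_sd: float
    auc: dict[str, float]
    roc: dict[str, dict]
    confusion: np.ndarray
    gain_ratio: pd.DataFrame
    n_cells: int
    per_repeat_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": self.params,
            "classes": self.classes,
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "gain_ratio": self.gain_ratio.to_dict(orient="records"),
            "n_cells": self.n_cells,
            "per_repeat_accuracy": self.per_repeat_accuracy,
        }


def train_forest(
    records: pd.DataFrame,
    params: list[str] | None = None,
    cv: CVPlan | None = None,
    forest_cfg: ForestConfig = ForestConfig(),
    method: str = "random_forest",
    label_col: str = "cell_class",
    seed: int | None = None,
) -> ClassifierReport:
    """Repeated cross-validated classification with pooled out-of-fold
    predictions.

    Per repeat, each fold's cells are predicted by a model trained on
    the complementary folds; accuracy (micro-averaged over the pooled
    predictions), one-vs-rest ROC/AUC per class, and the confusion
    matrix are averaged over repeats.  Rows with NaN in the selected
    columns are dropped with a warning.
    """
    params = params or [p for p in ALL_PARAMETERS if p in records.columns]
    data = records[params + [label_col]]
    if data[params].isna().any().any():
        import warnings
        n_bad = int(data[params].isna().any(axis=1).sum())
        warnings.warn(f"dropping {n_bad} cells with NaN features")
        data = data.dropna(subset=params)
    X = data[params].to_numpy(dtype=float)
    y = data[label_col].to_numpy()
    classes = sorted(pd.unique(y).tolist())
    if cv is None:
        cv = make_cv_plan(len(y), labels=y, seed=seed)
    if cv.n_cells != len(y):
        raise ValueError("CV plan size does not match record count")

    base_seed = (cv.seed if cv.seed >= 0 else 0)
    accs, aucs, rocs, confs = [], [], [], []
    for r in range(cv.n_repeats):
        proba = np.zeros((len(y), len(classes)))
        pred = np.empty(len(y), dtype=object)
        for f in range(cv.n_folds):
            test = cv.folds[r] == f
            train = ~test
            if len(np.unique(y[train])) < len(classes):
                import warnings
                warnings.warn(f"repeat {r} fold {f}: class missing from "
                              "training split")
            est = _build_estimator(method, forest_cfg,
                                   seed=(base_seed + 1000 * r + f) % (2**31))
            est.fit(X[train], y[train])
            p = est.predict_proba(X[test])
            cols = {c: i for i, c in enumerate(est.classes_)}
            for j, c in enumerate(classes):
                if c in cols:
                    proba[test, j] = p[:, cols[c]]
            pred[test] = est.predict(X[test])
        accs.append(float((pred == y).mean()))
        confs.append(confusion_matrix(y, pred.astype(str), labels=classes))
        rep_auc, rep_roc = {}, {}
        for j, c in enumerate(classes):
            rr = roc_ovr(proba[:, j], y == c)
            rep_auc[c] = rr["auc"]
            rep_roc[c] = rr
        aucs.append(rep_auc)
        rocs.append(rep_roc)

    gr = rank_by_gain_ratio(data, params, label_col=label_col)
    mean_auc = {c: float(np.mean([a[c] for a in aucs])) for c in classes}
    # representative curve: repeat with median accuracy
    mid = int(np.argsort(accs)[len(accs) // 2])
    return ClassifierReport(
        method=method, params=list(params), classes=classes,
        accuracy=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        auc=mean_auc, roc=rocs[mid], confusion=np.mean(confs, axis=0),
        gain_ratio=gr, n_cells=len(y), per_repeat_accuracy=accs)


def accuracy_vs_k(
    records: pd.DataFrame,
    ranked_params: list[str] | None = None,
    cv: CVPlan | None = None,
    forest_cfg: ForestConfig = ForestConfig(),
    label_col: str = "cell_class",
    seed: int | None = None,
    k_values: list[int] | None = None,
) -> pd.DataFrame:
    """Accuracy of the forest retrained on the top-k ranked parameters.

    ``ranked_params`` defaults to the gain-ratio ranking computed on
    ``records``.  Returns one row per k with the parameter added at that
    step.  The named preset ``FAD_LIFETIME_PRESET`` covers the
    FAD-channel-only configuration.
    """
    if ranked_params is None:
        ranked_params = rank_by_gain_ratio(
            records, label_col=label_col)["parameter"].tolist()
    ks = k_values or list(range(1, len(ranked_params) + 1))
    if max(ks) > len(ranked_params):
        raise ValueError("k exceeds the number of ranked parameters")
    y = records[label_col].to_numpy()
    if cv is None:
        cv = make_cv_plan(len(y), labels=y, seed=seed)
    rows = []
    for k in ks:
        rep = train_forest(records, ranked_params[:k], cv=cv,
                           forest_cfg=forest_cfg, label_col=label_col)
        rows.append({"k": k, "parameter_added": ranked_params[k - 1],
                     "accuracy": rep.accuracy,
                     "accuracy_sd": rep.accuracy_sd})
    return pd.DataFrame(rows)
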