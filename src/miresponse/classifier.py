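"""RBF-kernel SVM response classifier and its evaluation.

The predictor is a soft-margin support vector machine with the Gaussian
kernel ``K(xi, xj) = exp(-gamma ||xi - xj||^2)``; responders are class +1,
non-responders -1, and the predicted class is the sign of the decision
value ``f(x) = sum_i alpha_i y_i K(x_i, x) + b`` (the signed distance from
the separating hyperplane; an exact 0 maps to +1). Evaluation follows the
small-cohort protocol: repeated stratified 5-fold cross-validation with
train-only feature scaling inside each fold, sensitivity / specificity /
accuracy from pooled confusion counts, ROC curves from decision values
(AUC = Mann-Whitney probability with ties counted 1/2), and a two-sided
DeLong test for comparing correlated AUCs. A comparative-CT helper converts
qPCR cycle thresholds to 2^-ddCt fold changes for independent validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

RESPONDER = 1
NON_RESPONDER = -1


@dataclass
class ModelSpec:
    """RBF-SVM hyperparameters and the feature-scaling mode."""

    c: float = 1.0
    gamma: float | str = "scale"   # numeric, or "scale" = 1/(n_features * var)
    scale_mode: str = "zscore"     # "zscore" | "minmax" | "none"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.scale_mode not in ("zscore", "minmax", "none"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")


@dataclass
class ScalingStats:
    mode: str
    center: np.ndarray    # mean (zscore) or min (minmax)
    scale: np.ndarray     # population sd (zscore) or range (minmax)

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return np.asarray(x, dtype=float)
        return (np.asarray(x, dtype=float) - self.center) / self.scale


def scale_features(train: np.ndarray, test: np.ndarray | None = None,
                   mode: str = "zscore"):
    """Scale with statistics estimated on the training samples only.

    zscore uses the population standard deviation (ddof=0). A zero-variance
    (or zero-range) feature scales to 0 with a warning. minmax-scaled test
    values may fall outside [0, 1] when they exceed the training range.
    Returns (scaled train, scaled test or None, ScalingStats).
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    if mode == "none":
        stats = ScalingStats("none", np.zeros(train.shape[1]),
                             np.ones(train.shape[1]))
    elif mode == "zscore":
        center = train.mean(axis=0)
        scale = train.std(axis=0, ddof=0)
        if np.any(scale == 0):
            warnings.warn("zero-variance feature scaled to 0")
            scale = np.where(scale == 0, 1.0, scale)
        stats = ScalingStats("zscore", center, scale)
    elif mode == "minmax":
        lo, hi = train.min(axis=0), train.max(axis=0)
        rng = hi - lo
        if np.any(rng == 0):
            warnings.warn("zero-range feature scaled to 0")
            rng = np.where(rng == 0, 1.0, rng)
        stats = ScalingStats("minmax", lo, rng)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return (stats.apply(train),
            stats.apply(test) if test is not None else None,
            stats)


@dataclass
class TrainedModel:
    """A fitted RBF-SVM: support vectors, dual coefficients, bias, scaling."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray        # alpha_i * y_i per support vector
    intercept: float
    gamma: float
    c: float
    scaling: ScalingStats
    n_features: int

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[1]}")
        xs = self.scaling.apply(x)
        sq = (np.sum(xs ** 2, axis=1)[:, None]
              + np.sum(self.support_vectors ** 2, axis=1)[None, :]
              - 2.0 * xs @ self.support_vectors.T)
        k = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return k @ self.dual_coef + self.intercept


def _resolve_gamma(gamma: float | str, x: np.ndarray) -> float:
    if gamma == "scale":
        v = x.var()
        return 1.0 / (x.shape[1] * v) if v > 0 else 1.0 / x.shape[1]
    return float(gamma)


def train_svm_rbf(features: np.ndarray, labels: np.ndarray,
                  spec: ModelSpec | None = None) -> TrainedModel:
    """Fit the soft-margin RBF SVM (libsvm dual solver via scikit-learn).

    Labels must be in {+1, -1} with both classes present. Feature scaling
    per ``spec.scale_mode`` is folded into the returned model so prediction
    accepts raw inputs.
    """
    spec = spec or ModelSpec()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {RESPONDER, NON_RESPONDER}:
        raise ValueError("labels must contain both classes +1 and -1")
    xs, _, stats = scale_features(x, None, spec.scale_mode)
    gamma = _resolve_gamma(spec.gamma, xs)
    clf = SVC(C=spec.c, kernel="rbf", gamma=gamma, tol=1e-6)
    clf.fit(xs, y)
    # sklearn orders classes [-1, +1]; decision > 0 means class +1
    return TrainedModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        gamma=gamma, c=spec.c, scaling=stats, n_features=x.shape[1])


def predict(model: TrainedModel, features: np.ndarray):
    """Predicted labels in {+1, -1} and decision values; 0 maps to +1."""
    f = model.decision_function(features)
    labels = np.where(f >= 0, RESPONDER, NON_RESPONDER)
    return labels, f


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_labels(true: np.ndarray, pred: np.ndarray) -> "ConfusionCounts":
        true, pred = np.asarray(true), np.asarray(pred)
        return ConfusionCounts(
            tp=int(np.sum((true == RESPONDER) & (pred == RESPONDER))),
            tn=int(np.sum((true == NON_RESPONDER) & (pred == NON_RESPONDER))),
            fp=int(np.sum((true == NON_RESPONDER) & (pred == RESPONDER))),
            fn=int(np.sum((true == RESPONDER) & (pred == NON_RESPONDER))))

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def metrics(counts: ConfusionCounts):
    """(sensitivity, specificity, accuracy); undefined ratios are NaN."""
    if counts.n == 0:
        raise ValueError("no evaluated samples")
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else np.nan
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else np.nan
    if np.isnan(sens):
        warnings.warn("sensitivity undefined: no positive samples")
    if np.isnan(spec):
        warnings.warn("specificity undefined: no negative samples")
    acc = (counts.tp + counts.tn) / counts.n
    return float(sens), float(spec), float(acc)


def roc_auc(decision_values: np.ndarray, labels: np.ndarray):
    """ROC points and AUC (Mann-Whitney probability, ties count 1/2)."""
    y = np.asarray(labels)
    s = np.asarray(decision_values, dtype=float)
    if len(set(np.unique(y))) < 2:
        raise ValueError("both classes required for ROC")
    fpr, tpr, _ = roc_curve(y, s, pos_label=RESPONDER)
    auc = float(roc_auc_score(y == RESPONDER, s))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# ---------------------------------------------------------------------------
# repeated stratified k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    repeat: int
    fold: int
    counts: ConfusionCounts
    accuracy: float
    test_index: list[int]
    decision_values: list[float]
    true_labels: list[int]


@dataclass
class CVReport:
    """Per-fold and per-repeat cross-validation results.

    Per-repeat metrics pool confusion counts and decision values over the
    repeat's folds; the headline numbers average the repeats.
    """

    folds: list[FoldResult]
    repeats: pd.DataFrame   # accuracy, sensitivity, specificity, auc per repeat
    seed: int
    k: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.repeats["accuracy"].mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.repeats["sensitivity"].mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.repeats["specificity"].mean())

    @property
    def mean_auc(self) -> float:
        return float(self.repeats["auc"].mean())

    def summary_frame(self) -> pd.DataFrame:
        out = self.repeats.agg(["mean", "std"])
        return out


def kfold_cv(features: np.ndarray, labels: np.ndarray, k: int = 5,
             repeats: int = 5, spec: ModelSpec | None = None,
             seed: int = 0) -> CVReport:
    """Repeated stratified k-fold cross-validation of the RBF SVM.

    Folds are drawn per repeat from a seeded RNG; within each fold the
    scaler is fitted on the training part only. If stratification still
    yields a single-class test fold the repeat is re-drawn (bounded
    retries). Deterministic for a fixed seed.
    """
    spec = spec or ModelSpec()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(x) < k:
        raise ValueError("fewer samples than folds")
    if min(np.sum(y == RESPONDER), np.sum(y == NON_RESPONDER)) < 2:
        raise ValueError("each class needs at least 2 members")

    folds: list[FoldResult] = []
    repeat_rows = []
    for rep in range(repeats):
        for attempt in range(10):
            rs = (seed * 7919 + rep * 104729 + attempt) % (2 ** 31 - 1)
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            splits = list(splitter.split(x, y))
            if all(len(np.unique(y[te])) == 2 for _, te in splits):
                break
        else:
            raise RuntimeError("could not stratify folds with both classes")
        rep_counts = ConfusionCounts(0, 0, 0, 0)
        rep_scores: list[float] = []
        rep_true: list[int] = []
        for fold_i, (tr, te) in enumerate(splits):
            model = train_svm_rbf(x[tr], y[tr], spec)
            pred, dec = predict(model, x[te])
            counts = ConfusionCounts.from_labels(y[te], pred)
            folds.append(FoldResult(
                repeat=rep, fold=fold_i, counts=counts,
                accuracy=(counts.tp + counts.tn) / counts.n,
                test_index=[int(i) for i in te],
                decision_values=[float(v) for v in dec],
                true_labels=[int(v) for v in y[te]]))
            rep_counts = rep_counts + counts
            rep_scores.extend(dec)
            rep_true.extend(y[te])
        sens, specificity, acc = metrics(rep_counts)
        _, auc = roc_auc(np.array(rep_scores), np.array(rep_true))
        repeat_rows.append({"repeat": rep, "accuracy": acc,
                            "sensitivity": sens, "specificity": specificity,
                            "auc": auc})
    report = CVReport(folds=folds,
                      repeats=pd.DataFrame(repeat_rows).set_index("repeat"),
                      seed=seed, k=k)
    return report


# ---------------------------------------------------------------------------
# DeLong test for correlated ROC curves
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == RESPONDER]
    neg = scores[labels == NON_RESPONDER]
    m, n = len(pos), len(neg)
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r, neg_r = _midranks(pos), _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n                 # per positive
    v01 = 1.0 - (all_r[m:] - neg_r) / m           # per negative
    return auc, v10, v01


def compare_auc(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> dict:
    """Two-sided DeLong test for two correlated ROC curves.

    Returns auc_a, auc_b, the variance of the AUC difference, z and p.
    Identical score vectors give p = 1; a zero-variance difference with a
    non-zero AUC gap is reported as not computable (NaN) with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores and labels must be paired and equal-length")
    if len(set(np.unique(y))) < 2:
        raise ValueError("both classes required")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    if np.array_equal(a, b):
        return {"auc_a": float(auc_a), "auc_b": float(auc_b),
                "var_diff": 0.0, "z": 0.0, "p_value": 1.0}
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return {"auc_a": float(auc_a), "auc_b": float(auc_b),
                    "var_diff": 0.0, "z": 0.0, "p_value": 1.0}
        warnings.warn("DeLong variance is degenerate; p-value not computable")
        return {"auc_a": float(auc_a), "auc_b": float(auc_b),
                "var_diff": float(var), "z": np.nan, "p_value": np.nan}
    z = diff / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "var_diff": float(var), "z": float(z), "p_value": float(min(p, 1.0))}


def covariate_auc(values: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Univariate AUC of a clinical covariate used directly as a score.

    Orientation is chosen so the reported AUC is >= 0.5; the returned sign
    is +1 if higher values indicate response, else -1.
    """
    _, auc = roc_auc(np.asarray(values, dtype=float), labels)
    if auc >= 0.5:
        return auc, 1
    return 1.0 - auc, -1


def ddct_fold_change(ct_target_case: float, ct_ref_case: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Comparative-CT qPCR fold change, 2^-ddCt after reference normalization."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not v > 0:
            raise ValueError("Ct values must be positive")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
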