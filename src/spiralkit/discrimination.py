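"""Classifier-based discrimination: logistic score, ROC, Youden cut,
three-fold cross-validation, and the early-disease subset analysis.

The classifier is an 18-feature main-effects logistic regression — the six
spiral indices for the dominant hand, the non-dominant hand, and their
absolute between-hand difference — fit by maximum likelihood on features
standardized with training-set statistics. Discrimination is summarized by
the empirical ROC curve, its trapezoidal AUC (equivalent to the Mann-Whitney
U statistic scaled by the product of class sizes), and the sensitivity and
specificity at the Youden-optimal threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import roc_curve

from .indices import SubjectRecord, INDEX_NAMES

FEATURE_COLUMNS = [f"{side}_{name}" for side in ("dom", "nondom", "diff")
                   for name in INDEX_NAMES]

#: L2 penalty applied when the unpenalized MLE is unstable (separation)
RIDGE_FALLBACK_ALPHA = 1e-4

#: coefficient magnitude (on standardized features) treated as a
#: separation symptom; genuine effects on standardized scales stay well
#: below this
SEPARATION_COEF_LIMIT = 15.0


class SeparationWarning(UserWarning):
    pass


def feature_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject-level 18-column feature matrix plus label/covariate columns."""
    rows = []
    for r in records:
        row = {"subject_id": r.meta.subject_id, "label": r.meta.group,
               "duration": r.meta.disease_duration, "sex": r.meta.sex}
        for side, iset in (("dom", r.dom), ("nondom", r.nondom),
                           ("diff", r.diff)):
            for name in INDEX_NAMES:
                row[f"{side}_{name}"] = getattr(iset, name)
        rows.append(row)
    return pd.DataFrame(rows)


def _nll_and_grad(w, X, y, alpha):
    z = X @ w
    # stable log(1 + exp(z)) - y*z
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    g = X.T @ (expit(z) - y)
    if alpha > 0:
        nll += 0.5 * alpha * float(w[1:] @ w[1:])  # intercept unpenalized
        g = g + alpha * np.concatenate([[0.0], w[1:]])
    return nll, g


@dataclass
class LogisticModel:
    """Fitted logistic score function on standardized features."""

    coef: np.ndarray           # includes intercept at position 0
    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    ridged: bool = False

    def scores(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        Z = (X - self.mean) / self.scale
        return expit(self.coef[0] + Z @ self.coef[1:])


def fit_logistic(X, y, feature_names: Optional[list[str]] = None
                 ) -> LogisticModel:
    """Maximum-likelihood logistic regression of labels on features.

    Features are standardized with the training data's mean and sd. If the
    unpenalized likelihood is unbounded (complete or quasi-complete
    separation), a weak ridge penalty (``RIDGE_FALLBACK_ALPHA``) is applied
    and a :class:`SeparationWarning` is issued.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0/1")
    n, d = X.shape
    if n <= d:
        warnings.warn(f"only {n} records for {d} features; fit is unstable",
                      UserWarning, stacklevel=2)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = np.column_stack([np.ones(n), (X - mean) / scale])

    def solve(alpha):
        res = minimize(_nll_and_grad, np.zeros(d + 1), args=(Z, y, alpha),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
        return res

    res = solve(0.0)
    ridged = False
    if (not res.success) or np.max(np.abs(res.x)) > SEPARATION_COEF_LIMIT \
            or not np.all(np.isfinite(res.x)):
        warnings.warn("separation or non-convergence in logistic fit; "
                      f"refitting with ridge penalty {RIDGE_FALLBACK_ALPHA}",
                      SeparationWarning, stacklevel=2)
        res = solve(RIDGE_FALLBACK_ALPHA)
        ridged = True
    return LogisticModel(coef=res.x, mean=mean, scale=scale,
                         feature_names=list(feature_names or []),
                         ridged=ridged)


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cut: float = float("nan")
    sens_at_cut: float = float("nan")
    spec_at_cut: float = float("nan")


def roc_auc(scores, labels) -> RocResult:
    """Empirical ROC over all distinct score thresholds; trapezoidal AUC.

    Ties are handled by the rank convention (a tied pair contributes 1/2),
    which makes the AUC identical to Mann-Whitney U / (n1*n2). The Youden
    cut fields are filled in by :func:`youden_cut`.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    roc = RocResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auc=auc)
    return youden_cut(roc)


def youden_cut(roc: RocResult) -> RocResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (and then toward the higher
    threshold). A score is called positive when it is >= the cut.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    # roc_curve orders by descending threshold, so among ties (compared with
    # a float tolerance) the first maximum has the highest specificity
    best = int(np.flatnonzero(j >= np.max(j) - 1e-12)[0])
    roc.youden_cut = float(roc.thresholds[best])
    roc.sens_at_cut = float(roc.sensitivity[best])
    roc.spec_at_cut = float(roc.specificity[best])
    return roc


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CrossValResult:
    fold_aucs: list[float]
    mean_auc: float
    folds: list[np.ndarray]


def crossval_3fold(X, y, seed: int, n_folds: int = 3) -> CrossValResult:
    """Stratified random-partition cross-validation of the logistic model.

    The data are partitioned into ``n_folds`` label-stratified subsamples;
    each fold is scored by a model trained on the remaining folds and its
    held-out AUC recorded. Folds are disjoint and exhaustive with per-class
    sizes differing by at most one.
    """
    X = np.asarray(X, float)
    y01 = np.asarray(y)
    if y01.dtype.kind in "UOS":
        y01 = (y01 == "PD").astype(float)
    y01 = y01.astype(float)
    for cls in (0.0, 1.0):
        if np.sum(y01 == cls) < n_folds:
            raise ValueError(f"need >= {n_folds} records per class")
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        folds = _stratified_folds(y01, n_folds, rng)
        if all(np.unique(y01[f]).size == 2 for f in folds):
            break
    else:
        raise ValueError("could not draw folds with both classes present")
    aucs = []
    for k in range(n_folds):
        test = folds[k]
        train = np.sort(np.concatenate([folds[j] for j in range(n_folds)
                                        if j != k]))
        model = fit_logistic(X[train], y01[train])
        roc = roc_auc(model.scores(X[test]), y01[test])
        aucs.append(roc.auc)
    return CrossValResult(fold_aucs=[float(a) for a in aucs],
                          mean_auc=float(np.mean(aucs)), folds=folds)


@dataclass
class CohortDiscrimination:
    auc: float
    youden_cut: float
    sensitivity: float
    specificity: float
    cv: CrossValResult
    n_pd: int
    n_control: int


def analyze_features(features: pd.DataFrame, seed: int) -> CohortDiscrimination:
    """Full-cohort ROC/Youden analysis plus three-fold cross-validation."""
    X = features[FEATURE_COLUMNS].to_numpy(float)
    y = (features["label"] == "PD").to_numpy(float)
    model = fit_logistic(X, y, feature_names=FEATURE_COLUMNS)
    roc = roc_auc(model.scores(X), y)
    cv = crossval_3fold(X, y, seed=seed)
    return CohortDiscrimination(
        auc=roc.auc, youden_cut=roc.youden_cut,
        sensitivity=roc.sens_at_cut, specificity=roc.spec_at_cut,
        cv=cv, n_pd=int(y.sum()), n_control=int((1 - y).sum()))


def early_pd_analysis(features: pd.DataFrame, seed: int,
                      max_duration: float = 5.0) -> CohortDiscrimination:
    """Discrimination restricted to early disease (duration <= max_duration)
    versus all controls."""
    is_pd = features["label"] == "PD"
    early = is_pd & (features["duration"] <= max_duration)
    n_early = int(early.sum())
    if n_early < 3:
        raise ValueError(
            f"only {n_early} PD subjects with duration <= {max_duration}")
    subset = features[early | ~is_pd].reset_index(drop=True)
    return analyze_features(subset, seed=seed)
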