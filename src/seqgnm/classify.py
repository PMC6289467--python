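"""Disease/neutral variant classification from fluctuation features.

A plain logistic regression (intercept + features, with only a tiny ridge
for numerical conditioning) is evaluated with repeated stratified 80/20
train/test splits.  Performance is summarized by the per-split ROC AUC
(mean and maximum over splits) and by accuracy, sensitivity
(TP/(TP+FN), disease as the positive class) and selectivity — the
true-negative rate TN/(TN+FP) — at the 0.5 probability threshold.
All split seeds are recorded so a report reproduces exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "ClassifierReport",
    "threshold_metrics",
    "fit_logistic",
    "apply_trained",
    "evaluate",
]

POSITIVE_LABEL = "disease"
NEGATIVE_LABEL = "neutral"
#: inverse ridge strength: effectively unregularized, kept finite for conditioning
RIDGE_C = 1e6


@dataclass
class ClassifierReport:
    """Aggregate evaluation over repeated stratified train/test splits."""

    feature_names: list[str]
    seeds: list[int]
    aucs: list[float]
    accuracy: float
    sensitivity: float
    selectivity: float
    coefficients: np.ndarray  # per-split rows: [intercept, beta_1, ...]
    n_excluded: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def max_auc(self) -> float:
        return float(np.max(self.aucs))

    def to_dict(self) -> dict:
        return {
            "features": self.feature_names,
            "seeds": self.seeds,
            "auc_per_split": self.aucs,
            "mean_auc": self.mean_auc,
            "max_auc": self.max_auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "selectivity": self.selectivity,
            "mean_coefficients": self.coefficients.mean(axis=0).tolist(),
            "n_excluded": self.n_excluded,
        }


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "bif":
        return y.astype(int)
    ok = np.isin(y, [POSITIVE_LABEL, NEGATIVE_LABEL])
    if not ok.all():
        bad = sorted(set(y[~ok]))
        raise ValueError(f"unknown labels {bad}")
    return (y == POSITIVE_LABEL).astype(int)


def threshold_metrics(
    y_true: Sequence, probs: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, sensitivity and selectivity of calls at a probability cut.

    Sensitivity is the true-positive rate for the disease class;
    selectivity the true-negative rate for the neutral class.
    """
    y = _as_binary(y_true)
    p = np.asarray(probs, dtype=float)
    call = (p >= threshold).astype(int)
    tp = int(np.sum((call == 1) & (y == 1)))
    tn = int(np.sum((call == 0) & (y == 0)))
    fp = int(np.sum((call == 1) & (y == 0)))
    fn = int(np.sum((call == 0) & (y == 1)))
    return {
        "accuracy": (tp + tn) / y.size if y.size else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "selectivity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def fit_logistic(features: np.ndarray, labels: Sequence) -> LogisticRegression:
    """Fit the (effectively unregularized) logistic model."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(labels) == X.shape[1]:
        X = X.T
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = LogisticRegression(C=RIDGE_C, solver="lbfgs", max_iter=5000)
    model.fit(X, y)
    return model


def apply_trained(model: LogisticRegression, features: np.ndarray) -> pd.DataFrame:
    """Predicted disease probabilities and class calls for new variants.

    The call is ``disease`` iff the predicted probability is >= 0.5.  An
    empty feature matrix yields an empty frame.
    """
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        return pd.DataFrame({"probability": [], "call": []})
    X = np.atleast_2d(X)
    if X.shape[1] != model.coef_.shape[1]:
        if X.shape[0] == model.coef_.shape[1]:
            X = X.T
        else:
            raise ValueError(
                f"feature schema mismatch: model expects {model.coef_.shape[1]} "
                f"columns, got {X.shape[1]}"
            )
    probs = model.predict_proba(X)[:, 1]
    calls = np.where(probs >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame({"probability": probs, "call": calls})


def evaluate(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence,
    n_splits: int = 10,
    train_frac: float = 0.8,
    seeds: Sequence[int] | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Repeated stratified 80/20 evaluation of the logistic classifier.

    ``seeds`` (one per split, default ``seed .. seed + n_splits - 1``)
    drive the splits; splits are stratified so neither side of a split can
    be single-class.  Rows with missing features are excluded and counted
    in the report rather than failing.
    """
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    y = _as_binary(labels)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    complete = np.all(np.isfinite(X), axis=1)
    n_excluded = int(np.sum(~complete))
    X, y = X[complete], y[complete]
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 variants per class")
    if seeds is None:
        seeds = [seed + k for k in range(n_splits)]
    seeds = [int(s) for s in seeds]

    aucs: list[float] = []
    coefs: list[np.ndarray] = []
    metrics: list[dict[str, float]] = []
    for s in seeds:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=s
        )
        model = fit_logistic(X_tr, y_tr)
        probs = model.predict_proba(X_te)[:, 1]
        aucs.append(float(roc_auc_score(y_te, probs)))
        coefs.append(np.concatenate([model.intercept_, model.coef_.ravel()]))
        metrics.append(threshold_metrics(y_te, probs))
    return ClassifierReport(
        feature_names=names,
        seeds=list(seeds),
        aucs=aucs,
        accuracy=float(np.mean([m["accuracy"] for m in metrics])),
        sensitivity=float(np.mean([m["sensitivity"] for m in metrics])),
        selectivity=float(np.mean([m["selectivity"] for m in metrics])),
        coefficients=np.array(coefs),
        n_excluded=n_excluded,
    )


def roc_points(y_true: Sequence, probs: Sequence[float]) -> pd.DataFrame:
    """FPR/TPR pairs of the ROC curve for one set of predictions."""
    fpr, tpr, thr = roc_curve(_as_binary(y_true), np.asarray(probs, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
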