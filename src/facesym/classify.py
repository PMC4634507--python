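"""Two-class linear classification of asymmetry features with LOOCV.

A palsy screen from the 2D feature vector (forehead index, mouth index) is a
small-n, low-dimensional problem, so the classifiers are deliberately
simple: Fisher/Gaussian LDA with a pooled covariance, and a linear-kernel
SVM.  Evaluation is leave-one-out cross-validation with a single pooled
confusion matrix over all folds.

LDA is solved in closed form: ``w = S_pooled^{-1} (mu_pos - mu_neg)`` with
the bias placed from the class means and the log prior ratio; a small ridge
(1e-8 of the mean diagonal) is added only when the pooled covariance is
near-singular, which happens in degenerate toy data.  The linear SVM is
scikit-learn's SVC with a linear kernel.

The positive class for precision/recall defaults to ``"palsy"``; the
per-class breakdown for both conventions is always included in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .landmarks import InvalidInputError

__all__ = [
    "FittingError",
    "LinearClassifier",
    "CVReport",
    "fit_lda",
    "fit_svm_linear",
    "loocv",
    "metrics",
    "confusion_counts",
    "write_report",
    "read_report",
]

POSITIVE_LABEL = "palsy"

_COND_LIMIT = 1e10  # pooled covariance condition number above which ridge kicks in
_RIDGE = 1e-8       # ridge as a fraction of the mean covariance diagonal


class FittingError(ValueError):
    """Raised when a classifier cannot be fitted on the given data."""


@dataclass(frozen=True)
class LinearClassifier:
    """A fitted linear decision rule ``sign(w . x + b)``.

    ``classes`` is (negative label, positive label); the decision function is
    positive for the positive class.
    """

    weights: np.ndarray
    bias: float
    method: str
    classes: tuple[str, str]

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        neg, pos = self.classes
        return np.where(scores > 0, pos, neg)


def _class_split(X, y, positive_label=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    labels = sorted(np.unique(y).tolist())
    if len(labels) != 2:
        raise FittingError(f"need exactly two classes, got {labels}")
    if positive_label is None:
        positive_label = POSITIVE_LABEL if POSITIVE_LABEL in labels else labels[1]
    if positive_label not in labels:
        raise FittingError(f"positive label {positive_label!r} not among classes {labels}")
    negative_label = labels[0] if labels[1] == positive_label else labels[1]
    return X, y, str(negative_label), str(positive_label)


def fit_lda(
    X,
    y,
    priors: str = "empirical",
    positive_label: str | None = None,
) -> LinearClassifier:
    """Closed-form two-class LDA with pooled within-class covariance.

    ``priors`` is ``"empirical"`` (class frequencies) or ``"equal"``.
    """
    X, y, neg, pos = _class_split(X, y, positive_label)
    if priors not in ("empirical", "equal"):
        raise InvalidInputError("priors must be 'empirical' or 'equal'")
    X0, X1 = X[y == neg], X[y == pos]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    if np.allclose(mu0, mu1, rtol=0, atol=0):
        raise FittingError("identical class means: no discriminant direction exists")

    n = len(X)
    dof = max(n - 2, 1)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / dof
    if np.linalg.cond(S) > _COND_LIMIT:
        scale = float(np.mean(np.diag(S)))
        S = S + (_RIDGE * scale if scale > 0 else _RIDGE) * np.eye(S.shape[0])
        if np.linalg.cond(S) > 1 / np.finfo(float).eps:
            raise FittingError("pooled covariance singular even after regularization")

    w = np.linalg.solve(S, mu1 - mu0)
    if priors == "empirical":
        log_prior_ratio = float(np.log(len(X1) / len(X0)))
    else:
        log_prior_ratio = 0.0
    b = -0.5 * float(w @ (mu0 + mu1)) + log_prior_ratio
    if not np.any(w):
        raise FittingError("LDA produced an all-zero weight vector")
    return LinearClassifier(weights=w, bias=b, method="lda", classes=(neg, pos))


def fit_svm_linear(X, y, c: float = 1.0, positive_label: str | None = None) -> LinearClassifier:
    """Maximum-margin linear boundary (hinge loss, penalty ``c``)."""
    X, y, neg, pos = _class_split(X, y, positive_label)
    if c <= 0:
        raise InvalidInputError("SVM regularization strength c must be positive")
    # encode so the positive class is class 1 and coef_ signs are stable
    y01 = (y == pos).astype(int)
    svc = SVC(kernel="linear", C=c)
    svc.fit(X, y01)
    return LinearClassifier(
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        method="svm_linear",
        classes=(neg, pos),
    )


_FITTERS = {"lda": fit_lda, "svm_linear": fit_svm_linear}


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    """(accuracy, precision, recall) from confusion counts.

    Empty denominators yield NaN with a warning rather than an error.
    """
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise InvalidInputError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise InvalidInputError("confusion matrix is empty")
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive ground truth: recall undefined", stacklevel=2)
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    return accuracy, precision, recall


def confusion_counts(y_true, y_pred, positive_label: str) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    return tp, fp, fn, tn


@dataclass
class CVReport:
    """Pooled leave-one-out results: per-fold predictions plus one confusion matrix."""

    method: str
    combo: str
    positive_label: str
    folds: list  # (subject_id, true label, predicted label)
    skipped: list = field(default_factory=list)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "combo": self.combo,
            "positive_label": self.positive_label,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "per_class": self.per_class,
            "folds": [list(f) for f in self.folds],
            "skipped": list(self.skipped),
        }


def loocv(
    X,
    y,
    subject_ids: Sequence[str] | None = None,
    method: str = "lda",
    combo: str = "",
    positive_label: str | None = None,
    **fit_kwargs,
) -> CVReport:
    """Leave-one-out cross-validation with a pooled confusion matrix.

    Each subject is predicted by a classifier trained on all others.  A fold
    whose training set collapses to a single class is skipped with a warning
    and listed in the report.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = len(X)
    if n < 3:
        raise InvalidInputError(f"LOOCV needs at least 3 subjects, got {n}")
    if method not in _FITTERS:
        raise InvalidInputError(f"method must be one of {sorted(_FITTERS)}")
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n)]
    _, _, neg, pos = _class_split(X, y, positive_label)

    folds, skipped = [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            warnings.warn(
                f"fold {subject_ids[i]} skipped: training set has a single class",
                stacklevel=2,
            )
            skipped.append(str(subject_ids[i]))
            continue
        clf = _FITTERS[method](X[mask], y[mask], positive_label=pos, **fit_kwargs)
        pred = clf.predict(X[i:i + 1])[0]
        folds.append((str(subject_ids[i]), str(y[i]), str(pred)))

    true = [f[1] for f in folds]
    pred = [f[2] for f in folds]
    tp, fp, fn, tn = confusion_counts(true, pred, pos)
    acc, prec, rec = metrics(tp, fp, fn, tn)

    per_class = {}
    for label in (neg, pos):
        ctp, cfp, cfn, ctn = confusion_counts(true, pred, label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cacc, cprec, crec = metrics(ctp, cfp, cfn, ctn)
        per_class[label] = {"precision": cprec, "recall": crec}

    return CVReport(
        method=method,
        combo=combo,
        positive_label=pos,
        folds=folds,
        skipped=skipped,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=acc,
        precision=prec,
        recall=rec,
        per_class=per_class,
    )


def write_report(path, reports) -> None:
    """Write one or more CVReports as a JSON list."""
    if isinstance(reports, CVReport):
        reports = [reports]
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))


def read_report(path) -> list:
    return json.loads(Path(path).read_text())
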