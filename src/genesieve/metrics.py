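"""Multiclass classification metrics: per-class precision/recall/F1,
accuracy, macro and class-weighted F1, and the multiclass Matthews
correlation coefficient.

Conventions for degenerate denominators: a class with no predicted
(or no true) positives gets precision (recall) 0, and F1 is 0 when
precision + recall = 0; MCC is 0 when either one-hot covariance term
vanishes (e.g. a constant prediction). Class weights w_i are the
proportions of each class among the *true* labels, so synthetic
oversampled rows — which never enter evaluation — cannot shift them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EvalResult:
    """Full metric suite for one evaluated prediction vector."""

    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    per_class_f1: dict[str, float]
    accuracy: float
    macro_f1: float
    weighted_f1: float
    mcc: float
    class_weights: dict[str, float]

    @property
    def n_classes(self) -> int:
        return len(self.per_class_f1)

    def row(self) -> dict[str, float | str]:
        """Flat dict for tabular serialization (one summary row)."""
        out: dict[str, float | str] = {}
        for cls in sorted(self.per_class_f1):
            out[f"F1_{cls}"] = self.per_class_f1[cls]
        out["ACC"] = self.accuracy
        out["MCC"] = self.mcc
        out["macro_F1"] = self.macro_f1
        out["weighted_F1"] = self.weighted_f1
        return out


def _multiclass_mcc(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> float:
    # covariance form on one-hot matrices: cov(X,Y)/sqrt(cov(X,X) cov(Y,Y))
    n = len(y_true)
    X = np.zeros((n, len(classes)))
    Y = np.zeros((n, len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    X[np.arange(n), [pos[str(v)] for v in y_true]] = 1.0
    Y[np.arange(n), [pos[str(v)] for v in y_pred]] = 1.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float((Xc * Yc).sum())
    cov_xx = float((Xc * Xc).sum())
    cov_yy = float((Yc * Yc).sum())
    if cov_xx == 0.0 or cov_yy == 0.0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def evaluate(y_true, y_pred) -> EvalResult:
    """Evaluate predicted against true labels.

    Classes are the distinct true labels; a predicted label outside
    that set is rejected.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length non-empty vectors")
    classes = sorted({str(v) for v in y_true})
    unknown = {str(v) for v in y_pred} - set(classes)
    if unknown:
        raise ValueError(f"predicted label(s) not in true label set: {sorted(unknown)}")

    n = y_true.size
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    weights: dict[str, float] = {}
    ts = np.array([str(v) for v in y_true])
    ps = np.array([str(v) for v in y_pred])
    for cls in classes:
        tp = float(np.sum((ts == cls) & (ps == cls)))
        fp = float(np.sum((ts != cls) & (ps == cls)))
        fn = float(np.sum((ts == cls) & (ps != cls)))
        precision[cls] = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall[cls] = tp / (tp + fn) if tp + fn > 0 else 0.0
        pr = precision[cls] + recall[cls]
        f1[cls] = 2 * precision[cls] * recall[cls] / pr if pr > 0 else 0.0
        weights[cls] = float(np.sum(ts == cls)) / n

    return EvalResult(
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        accuracy=float(np.sum(ts == ps)) / n,
        macro_f1=float(np.mean([f1[c] for c in classes])),
        weighted_f1=float(sum(weights[c] * f1[c] for c in classes)),
        mcc=_multiclass_mcc(ts, ps, classes),
        class_weights=weights,
    )
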