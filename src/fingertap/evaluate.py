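"""Evaluation metrics for ordinal severity predictions.

Two accuracies are reported: exact agreement ("t1") and within-one-point
agreement ("t2"), the latter acknowledging that even expert raters disagree
by one point on a substantial share of recordings.  Precision, recall and
F-beta are computed one-vs-rest per class and macro-averaged (unweighted)
over the classes present in the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

N_CLASSES = 5


def _check_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.size != truth.size or pred.size == 0:
        raise ValidationError("pred and truth must have equal nonzero length")
    return pred, truth


def accuracy_t1(pred, truth) -> float:
    """Fraction of exact matches."""
    pred, truth = _check_pair(pred, truth)
    return float(np.mean(pred == truth))


def accuracy_t2(pred, truth) -> float:
    """Fraction of predictions within +/- 1 of the true score."""
    pred, truth = _check_pair(pred, truth)
    return float(np.mean(np.abs(pred - truth) <= 1))


def confusion_matrix(pred, truth) -> np.ndarray:
    """5x5 count matrix; rows = truth, columns = prediction."""
    pred, truth = _check_pair(pred, truth)
    if np.any((pred < 0) | (pred >= N_CLASSES) | (truth < 0) | (truth >= N_CLASSES)):
        raise ValidationError("scores must be in 0-4")
    mat = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(mat, (truth, pred), 1)
    return mat


def precision_recall_f(
    pred, truth, beta: float = 1.0
) -> dict:
    """One-vs-rest precision/recall/F-beta per class plus macro averages.

    F_beta = (1 + beta^2) P R / (beta^2 P + R).  A class with zero predicted
    positives gets precision 0 (flagged); macro averages run over the classes
    present in the truth so they stay defined.
    """
    if beta <= 0:
        raise ValidationError("beta must be positive")
    pred, truth = _check_pair(pred, truth)
    per_class: dict[int, dict[str, float]] = {}
    flags: list[str] = []
    present = sorted(set(truth.tolist()))
    for c in range(N_CLASSES):
        tp = float(np.sum((pred == c) & (truth == c)))
        fp = float(np.sum((pred == c) & (truth != c)))
        fn = float(np.sum((pred != c) & (truth == c)))
        if tp + fp == 0:
            precision = 0.0
            flags.append(f"class {c}: no predicted positives")
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        denom = beta**2 * precision + recall
        fbeta = (1 + beta**2) * precision * recall / denom if denom > 0 else 0.0
        per_class[c] = {"precision": precision, "recall": recall, "f": fbeta}
    macro = {
        key: float(np.mean([per_class[c][key] for c in present]))
        for key in ("precision", "recall", "f")
    }
    return {"per_class": per_class, "macro": macro, "beta": beta, "flags": flags}


@dataclass
class EvalReport:
    """Full evaluation summary for one prediction set."""

    accuracy_t1: float
    accuracy_t2: float
    confusion: np.ndarray
    per_class: dict
    macro: dict
    beta: float = 1.0
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy_t1": self.accuracy_t1,
            "accuracy_t2": self.accuracy_t2,
            "confusion_matrix": self.confusion.tolist(),
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro": self.macro,
            "beta": self.beta,
            "flags": list(self.flags),
        }


def evaluate(pred, truth, beta: float = 1.0) -> EvalReport:
    """Compute every metric at once."""
    prf = precision_recall_f(pred, truth, beta=beta)
    return EvalReport(
        accuracy_t1=accuracy_t1(pred, truth),
        accuracy_t2=accuracy_t2(pred, truth),
        confusion=confusion_matrix(pred, truth),
        per_class=prf["per_class"],
        macro=prf["macro"],
        beta=beta,
        flags=prf["flags"],
    )


def annotator_agreement(rater1, rater2) -> tuple[float, float, float]:
    """(complete %, acceptable %, none %) agreement between two raters.

    Complete: identical scores.  Acceptable: differ by at most 1 (a superset
    of complete).  None: differ by more than 1.  Acceptable + none = 100.
    """
    r1, r2 = _check_pair(rater1, rater2)
    diff = np.abs(r1 - r2)
    complete = float(np.mean(diff == 0)) * 100.0
    acceptable = float(np.mean(diff <= 1)) * 100.0
    none = float(np.mean(diff > 1)) * 100.0
    return complete, acceptable, none
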