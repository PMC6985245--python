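"""Selection metrics for viability sorting.

Confusion-matrix rates, ROC/AUC under the strict ``viable iff P > T`` rule,
and the sorting-specific quantities: predicted clone recovery and growth
increase (GI).

Naming note.  In this application the "false positive rate" is conventionally
written as TN/(TN+FP) — i.e. the accuracy on dead cells, a *specificity*.  To
keep ROC/AUC on standard axes while staying consistent with the GI formula's
``(1 - FPR)`` term, this module exposes that quantity under the honest name
:func:`dead_recognition_rate` (alias :func:`fpr_paper`) and uses its
complement, the *dead-pass rate* FP/(TN+FP) — the fraction of dead cells the
classifier lets through — as the ROC x-axis.

With viable fraction ``c_v``, the fraction of classifier-passed single cells
expected to grow is

    recovery(T) = c_v*TPR / (c_v*TPR + (1-c_v)*dead_pass),

and the growth increase over not using the classifier is GI = recovery / c_v,
bounded by 1/c_v for a perfect classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "OperatingCurve",
    "SampleComposition",
    "confusion",
    "tpr",
    "dead_recognition_rate",
    "fpr_paper",
    "dead_pass_rate",
    "accuracy",
    "roc_auc",
    "predicted_clone_recovery",
    "growth_increase",
    "growth_increase_from_recoveries",
    "pooled_recovery",
    "classify",
]

VIABLE, DEAD = "viable", "dead"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class OperatingCurve:
    """ROC operating points indexed by threshold, ascending in T.

    ``tpr_at`` and ``deadpass_at`` are the rates under the strict P > T rule;
    both are non-increasing in T.
    """

    thresholds: np.ndarray
    tpr_at: np.ndarray
    deadpass_at: np.ndarray

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class SampleComposition:
    n: int
    c_v: float

    def __post_init__(self):
        if not 0.0 <= self.c_v <= 1.0:
            raise ValueError("c_v must be in [0, 1]")
        if self.n <= 0:
            raise ValueError("n must be positive")


def classify(P, T: float):
    """Threshold rule: viable iff P > T, strictly (P == T counts as dead)."""
    P = np.asarray(P, dtype=float)
    out = np.where(P > T, VIABLE, DEAD)
    return out if out.ndim else str(out)


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    return arr == VIABLE


def confusion(labels, preds) -> ConfusionCounts:
    """Count TP/FP/TN/FN with viable as the positive class.

    ``labels`` and ``preds`` may be 'viable'/'dead' strings or booleans/0-1
    (truthy = viable).
    """
    y, p = _as_binary(labels), _as_binary(preds)
    if y.shape != p.shape:
        raise ValueError("labels and preds must have equal length")
    return ConfusionCounts(
        TP=int(np.sum(y & p)),
        FP=int(np.sum(~y & p)),
        TN=int(np.sum(~y & ~p)),
        FN=int(np.sum(y & ~p)),
    )


def tpr(cc: ConfusionCounts) -> float:
    """True positive rate TP/(TP+FN): accuracy on the truly viable cells."""
    denom = cc.TP + cc.FN
    if denom == 0:
        raise ZeroDivisionError("TPR undefined: no truly viable cells in sample")
    return cc.TP / denom


def dead_recognition_rate(cc: ConfusionCounts) -> float:
    """Accuracy on dead cells, TN/(TN+FP) — a specificity."""
    denom = cc.TN + cc.FP
    if denom == 0:
        raise ZeroDivisionError("dead-recognition rate undefined: no dead cells")
    return cc.TN / denom


#: alias kept for fidelity with the field's occasional use of "FPR" for TN/(TN+FP)
fpr_paper = dead_recognition_rate


def dead_pass_rate(cc: ConfusionCounts) -> float:
    """Fraction of dead cells the classifier passes: FP/(TN+FP)."""
    return 1.0 - dead_recognition_rate(cc)


def accuracy(cc: ConfusionCounts) -> float:
    """Overall accuracy (TP+TN)/(TP+TN+FP+FN)."""
    if cc.total == 0:
        raise ZeroDivisionError("accuracy undefined on an empty sample")
    return (cc.TP + cc.TN) / cc.total


def roc_auc(labels, scores) -> tuple[OperatingCurve, float]:
    """ROC curve and trapezoidal AUC over (x = dead-pass rate, y = TPR).

    The threshold sweep covers every distinct score plus the T = 0 and T = 1
    endpoints, under the strict P > T rule; the T = 0 row is reported as the
    gate-off (accept-all) limit (1, 1).  The trapezoidal AUC equals the
    tie-corrected pairwise statistic: the probability that a uniformly chosen
    viable cell outscores a uniformly chosen dead cell, ties counting 1/2.
    """
    y = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")

    thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    # P > T for each threshold; vectorized over the sweep
    pos_scores, neg_scores = np.sort(scores[y]), np.sort(scores[~y])
    # count of scores strictly greater than t = n - searchsorted(sorted, t, 'right')
    tp = n_pos - np.searchsorted(pos_scores, thresholds, side="right")
    fp = n_neg - np.searchsorted(neg_scores, thresholds, side="right")
    tpr_at = tp / n_pos
    deadpass_at = fp / n_neg
    # prepend the gate-off (accept-all) limit so the curve always spans
    # (1,1) -> (0,0); when some score equals zero exactly this adds a second
    # vertex at T = 0 besides the strict P > 0 operating point
    if tpr_at[0] != 1.0 or deadpass_at[0] != 1.0:
        thresholds = np.concatenate([[0.0], thresholds])
        tpr_at = np.concatenate([[1.0], tpr_at])
        deadpass_at = np.concatenate([[1.0], deadpass_at])

    curve = OperatingCurve(
        thresholds=thresholds, tpr_at=tpr_at, deadpass_at=deadpass_at
    )
    # ascending thresholds give descending (x, y); integrate in ascending x
    auc = float(np.trapezoid(tpr_at[::-1], deadpass_at[::-1]))
    return curve, auc


def predicted_clone_recovery(c_v: float, TPR: float, dead_pass: float) -> float:
    """Expected fraction of classifier-passed wells that grow a colony."""
    for name, v in (("c_v", c_v), ("TPR", TPR), ("dead_pass", dead_pass)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    passed = c_v * TPR + (1.0 - c_v) * dead_pass
    if passed == 0.0:
        raise ZeroDivisionError(
            "recovery undefined: classifier passes nothing at this operating point"
        )
    return c_v * TPR / passed


def growth_increase(c_v: float, TPR: float, dead_pass: float) -> float:
    """GI: factor by which the classifier multiplies the per-well colony yield.

    GI = recovery / c_v; GI = 1 for an accept-all classifier, at most 1/c_v.
    """
    if c_v <= 0.0:
        raise ZeroDivisionError("GI undefined for c_v = 0")
    return predicted_clone_recovery(c_v, TPR, dead_pass) / c_v


def growth_increase_from_recoveries(recovery_with: float, recovery_without: float) -> float:
    """Empirical GI as a ratio of measured clone recoveries.

    Returns the exact ratio; round to two decimals when comparing against
    conventionally reported figures.
    """
    if recovery_without <= 0.0:
        raise ZeroDivisionError("GI undefined: zero baseline recovery")
    return recovery_with / recovery_without


def pooled_recovery(components: list[SampleComposition]) -> float:
    """Pool campaigns: integer colony counts per component over total wells."""
    if not components:
        raise ValueError("pooled_recovery requires at least one component")
    colonies = sum(round(c.c_v * c.n) for c in components)
    total = sum(c.n for c in components)
    return colonies / total
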