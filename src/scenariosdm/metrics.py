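"""Presence/absence evaluation metrics and the composite gamma model score.

The composite score rewards each of four metrics (CSI, Kappa, AUC, TSS) with
weight 0.5 when it clears a per-metric quality threshold and 0.3 otherwise,
then averages:

    gamma = (1/4) * sum_m  K_m * (0.5 if K_m > t_m else 0.3),
    t = {CSI: 0.3, Kappa: 0.4, AUC: 0.9, TSS: 0.7}

so gamma is in [0, 0.5] for metrics in [0, 1] and is monotone
non-decreasing in every metric.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

ConfusionMetrics = namedtuple("ConfusionMetrics", "sensitivity specificity tss kappa csi")


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion-derived statistics at the optimal threshold, plus AUC."""

    tss: float
    roc: float
    kappa: float
    csi: float
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    optimal_threshold: float = float("nan")
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass(frozen=True)
class GammaWeights:
    """Thresholds and conditional weights of the composite score."""

    thresholds: dict = field(
        default_factory=lambda: {"csi": 0.3, "kappa": 0.4, "roc": 0.9, "tss": 0.7}
    )
    above_weight: float = 0.5
    below_weight: float = 0.3
    divisor: int = 4


DEFAULT_GAMMA_WEIGHTS = GammaWeights()


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Sensitivity, specificity, TSS, Cohen's kappa and CSI from counts."""
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("degenerate confusion table: one observed class is empty")
    n = tp + fp + fn + tn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    tss = sens + spec - 1.0
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    csi = tp / (tp + fp + fn) if (tp + fp + fn) > 0 else 0.0
    return ConfusionMetrics(sens, spec, tss, kappa, csi)


def auc_score(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one label class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def optimize_threshold(scores, labels):
    """TSS-maximizing binarization threshold and the metrics attained there.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores (plus one candidate below the minimum); ties in TSS are broken
    toward the smaller threshold. Returns ``(threshold, EvalMetrics)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold optimization needs both label classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        candidates = np.array([uniq[0] - 0.5])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        candidates = np.concatenate([[uniq[0] - (uniq[1] - uniq[0]) / 2.0], mids])
    pos = labels == 1
    best = None
    for thr in candidates:  # ascending, so strict '>' keeps the smallest tie
        pred = scores > thr
        tp = int(np.sum(pred & pos))
        fp = int(np.sum(pred & ~pos))
        fn = int(np.sum(~pred & pos))
        tn = int(np.sum(~pred & ~pos))
        if tp + fn == 0 or fp + tn == 0:
            continue
        cm = confusion_metrics(tp, fp, fn, tn)
        if best is None or cm.tss > best[1].tss + 1e-12:
            best = (float(thr), cm, (tp, fp, fn, tn))
    thr, cm, counts = best
    metrics = EvalMetrics(
        tss=cm.tss,
        roc=auc_score(scores, labels),
        kappa=cm.kappa,
        csi=cm.csi,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        optimal_threshold=thr,
        tp=counts[0],
        fp=counts[1],
        fn=counts[2],
        tn=counts[3],
    )
    return thr, metrics


def gamma_score(
    metrics: EvalMetrics | None = None,
    *,
    csi: float | None = None,
    kappa: float | None = None,
    roc: float | None = None,
    tss: float | None = None,
    weights: GammaWeights = DEFAULT_GAMMA_WEIGHTS,
) -> float:
    """Composite conditional-weight model score (see module docstring).

    Accepts either an ``EvalMetrics`` or the four metric values by keyword.
    """
    if metrics is not None:
        csi, kappa, roc, tss = metrics.csi, metrics.kappa, metrics.roc, metrics.tss
    values = {"csi": csi, "kappa": kappa, "roc": roc, "tss": tss}
    if any(v is None for v in values.values()):
        raise ValueError("all four metrics (csi, kappa, roc, tss) are required")
    total = 0.0
    for name, value in values.items():
        w = weights.above_weight if value > weights.thresholds[name] else weights.below_weight
        total += value * w
    return total / weights.divisor
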