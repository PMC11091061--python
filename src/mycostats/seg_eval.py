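"""Instance-segmentation evaluation: mask IoU, AP/mAP, confidence summaries.

Predictions and ground truths are pixel masks with a class label and a
confidence score (ground truth carries confidence 1).  Evaluation is
class-wise: a prediction can only match an unmatched ground-truth instance
of the same class in the same image, greedily in descending confidence
order, taking the highest-IoU candidate at or above the IoU threshold.
AP is the 101-point interpolated area under the precision-recall curve on
a 0-100 scale; the headline AP averages IoU thresholds 0.50:0.05:0.95 and
mAP averages classes with at least one ground-truth instance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .annotation_geometry import PolygonShape, rasterize_pixels

__all__ = [
    "DEFAULT_IOU_THRESHOLDS",
    "MaskInstance",
    "EvalReport",
    "mask_iou",
    "match_instances",
    "average_precision",
    "evaluate_all",
    "confidence_summary",
    "compare_class_frequencies",
]

DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class MaskInstance:
    """One instance mask: pixel set, class label and confidence."""

    image_id: str
    class_label: str
    pixels: frozenset
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("mask must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @classmethod
    def from_polygon(
        cls, shape: PolygonShape, image_id: str, width: int, height: int, confidence: float = 1.0
    ) -> "MaskInstance":
        pts = rasterize_pixels(shape, width, height)
        return cls(image_id, shape.class_label, frozenset(map(tuple, pts)), confidence)


def mask_iou(a: MaskInstance, b: MaskInstance) -> float:
    """Intersection-over-union of two masks in the same image."""
    if a.image_id != b.image_id:
        raise ValueError("IoU is only defined for masks in the same image")
    inter = len(a.pixels & b.pixels)
    union = len(a.pixels | b.pixels)
    return inter / union


def _greedy_match(preds: Sequence[MaskInstance], truths: Sequence[MaskInstance], iou_threshold: float):
    """Greedy confidence-ordered matching within one image and class.

    Returns a TP/FP flag per prediction in global descending-confidence
    order (ties broken by input order via stable sort).
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    matched: set[int] = set()
    flags = []
    for i in order:
        p = preds[i]
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if j in matched or t.image_id != p.image_id:
                continue
            iou = mask_iou(p, t)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched.add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return flags, matched


def match_instances(
    preds: Sequence[MaskInstance], truths: Sequence[MaskInstance], iou_threshold: float = 0.5
) -> tuple[int, int, int]:
    """(TP, FP, FN) over all classes and images at one IoU threshold."""
    tp = fp = fn = 0
    classes = {m.class_label for m in preds} | {m.class_label for m in truths}
    for cls in classes:
        p_cls = [p for p in preds if p.class_label == cls]
        t_cls = [t for t in truths if t.class_label == cls]
        flags, matched = _greedy_match(p_cls, t_cls, iou_threshold)
        tp += sum(flags)
        fp += len(flags) - sum(flags)
        fn += len(t_cls) - len(matched)
    return tp, fp, fn


def average_precision(
    preds: Sequence[MaskInstance],
    truths: Sequence[MaskInstance],
    class_label: str,
    iou_threshold: float,
    n_interp: int = 101,
) -> float:
    """101-point interpolated AP (0-100 scale) for one class and threshold.

    With no ground truths the class is skipped (NaN) unless predictions
    exist, in which case AP is 0.  AP is invariant to order-preserving
    confidence rescaling.
    """
    p_cls = [p for p in preds if p.class_label == class_label]
    t_cls = [t for t in truths if t.class_label == class_label]
    if not t_cls:
        return 0.0 if p_cls else math.nan
    if not p_cls:
        return 0.0
    flags, _ = _greedy_match(p_cls, t_cls, iou_threshold)
    tp = np.cumsum(flags)
    fp = np.cumsum([not f for f in flags])
    recall = tp / len(t_cls)
    precision = tp / (tp + fp)
    grid = np.linspace(0.0, 1.0, n_interp)
    interp = np.zeros_like(grid)
    for k, r in enumerate(grid):
        ok = recall >= r - 1e-12
        interp[k] = precision[ok].max() if ok.any() else 0.0
    return float(interp.mean() * 100.0)


@dataclass
class EvalReport:
    """Per-class and aggregate AP metrics plus class frequency bookkeeping."""

    per_class_ap: dict[str, float] = field(default_factory=dict)
    per_class_ap50: dict[str, float] = field(default_factory=dict)
    map: float = math.nan
    map50: float = math.nan
    class_frequencies: dict[str, tuple[int, int]] = field(default_factory=dict)
    iou_thresholds: tuple[float, ...] = DEFAULT_IOU_THRESHOLDS


def evaluate_all(
    preds: Sequence[MaskInstance],
    truths: Sequence[MaskInstance],
    iou_thresholds: Sequence[float] = DEFAULT_IOU_THRESHOLDS,
    classes: Iterable[str] | None = None,
) -> EvalReport:
    """Full evaluation: per-class AP over the threshold grid, AP50, mAP, mAP50.

    ``classes`` defaults to every class with at least one ground-truth
    instance; mAP is their unweighted mean.
    """
    if classes is None:
        classes = sorted({t.class_label for t in truths})
    report = EvalReport(iou_thresholds=tuple(iou_thresholds))
    for cls in classes:
        aps = [average_precision(preds, truths, cls, thr) for thr in iou_thresholds]
        report.per_class_ap[cls] = float(np.mean(aps)) if not any(math.isnan(a) for a in aps) else math.nan
        report.per_class_ap50[cls] = average_precision(preds, truths, cls, 0.5)
        report.class_frequencies[cls] = (
            sum(p.class_label == cls for p in preds),
            sum(t.class_label == cls for t in truths),
        )
    vals = [v for v in report.per_class_ap.values() if not math.isnan(v)]
    vals50 = [v for v in report.per_class_ap50.values() if not math.isnan(v)]
    report.map = float(np.mean(vals)) if vals else math.nan
    report.map50 = float(np.mean(vals50)) if vals50 else math.nan
    return report


def confidence_summary(
    preds: Sequence[MaskInstance], threshold: float = 0.7, bins: int = 10
) -> dict[str, dict]:
    """Per-class confidence histograms on [threshold, 1] with sample skewness.

    Left-skewed (negative skewness) distributions indicate mass piled near
    1, i.e. high certainty in the assigned labels.  Classes with no
    surviving predictions get an empty histogram.
    """
    edges = np.linspace(threshold, 1.0, bins + 1)
    out: dict[str, dict] = {}
    for cls in sorted({p.class_label for p in preds}):
        conf = np.array([p.confidence for p in preds if p.class_label == cls and p.confidence >= threshold])
        if conf.size == 0:
            out[cls] = {"hist": np.zeros(bins, dtype=int), "edges": edges, "skewness": math.nan, "n": 0}
            continue
        hist, _ = np.histogram(conf, bins=edges)
        skew = 0.0 if np.ptp(conf) == 0 else float(stats.skew(conf))
        out[cls] = {"hist": hist, "edges": edges, "skewness": skew, "n": int(conf.size)}
    return out


# ---------------------------------------------------------------------------
# class-frequency comparison (Fisher's exact test on a 2 x K table)


def _log_table_prob(row1: np.ndarray, col_sums: np.ndarray, n1: int, n_total: int) -> float:
    """Log multivariate-hypergeometric probability of row 1 given margins."""
    return float(
        np.sum(gammaln(col_sums + 1) - gammaln(row1 + 1) - gammaln(col_sums - row1 + 1))
        - (gammaln(n_total + 1) - gammaln(n1 + 1) - gammaln(n_total - n1 + 1))
    )


def _enumerate_pvalue(col_sums: np.ndarray, n1: int, logp_obs: float) -> float:
    """Sum null probabilities of all tables no more probable than observed."""
    n_total = int(col_sums.sum())
    K = len(col_sums)
    total = 0.0

    def rec(k: int, remaining: int, row1: list[int]) -> None:
        nonlocal total
        if k == K - 1:
            if remaining <= col_sums[k]:
                full = np.array(row1 + [remaining])
                lp = _log_table_prob(full, col_sums, n1, n_total)
                if lp <= logp_obs + 1e-9:
                    total += math.exp(lp)
            return
        tail_capacity = int(col_sums[k + 1 :].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(col_sums[k]), remaining)
        for a in range(lo, hi + 1):
            rec(k + 1, remaining - a, row1 + [a])

    rec(0, n1, [])
    return min(total, 1.0)


def compare_class_frequencies(
    pred_counts: Sequence[int],
    truth_counts: Sequence[int],
    max_tables: float = 2e6,
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> tuple[float, str]:
    """Fisher's exact test that two class-frequency vectors share a distribution.

    Builds the 2 x K contingency table (predictions vs ground truth) and
    computes the exact conditional p-value by enumeration when the table is
    small enough, otherwise by seeded Monte Carlo sampling of tables with
    fixed margins.  Returns ``(p, method)``.
    """
    a = np.asarray(pred_counts, dtype=int)
    b = np.asarray(truth_counts, dtype=int)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the class set")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("all-zero contingency table")
    if a.size == 1:
        return 1.0, "degenerate-1-column"
    col_sums = a + b
    n1 = int(a.sum())
    n_total = int(col_sums.sum())
    logp_obs = _log_table_prob(a, col_sums, n1, n_total)

    n_tables_bound = float(np.prod(np.minimum(col_sums, n1) + 1.0))
    if n_tables_bound <= max_tables:
        return _enumerate_pvalue(col_sums, n1, logp_obs), "exact-enumeration"

    rng = np.random.default_rng(seed)
    sampler = stats.random_table([n1, n_total - n1], col_sums)
    tables = sampler.rvs(n_mc, random_state=rng)
    row1 = tables[:, 0, :]
    lp = (
        np.sum(gammaln(col_sums + 1) - gammaln(row1 + 1) - gammaln(col_sums - row1 + 1), axis=1)
        - (gammaln(n_total + 1) - gammaln(n1 + 1) - gammaln(n_total - n1 + 1))
    )
    p = float(np.mean(lp <= logp_obs + 1e-9))
    return p, "monte-carlo"
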