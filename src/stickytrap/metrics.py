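"""Detection evaluation: matching, P/R/F1, PR-curve AP/mAP, confusion matrix.

Matching is the standard greedy protocol: predictions in descending score
order each claim the unclaimed ground-truth box of highest IoU above the
threshold.  Precision, recall and F1 follow the usual tp/fp/fn definitions
with the 0/0 -> 0 convention.  Average precision is the area under the
all-point-interpolated precision-recall curve (monotone precision envelope),
and mAP averages per-class AP over the classes present in the ground truth.
The confusion matrix adds a background class: missed truths count as
(truth, background), spurious predictions as (background, prediction), and
its spatial matching is class-agnostic so genuine misclassifications land in
off-diagonal cells instead of being booked as a miss plus a false alarm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .boxes import DetectionSet, iou

__all__ = [
    "MatchResult",
    "ConfusionMatrix",
    "match",
    "prf1",
    "average_precision",
    "per_class_ap",
    "mean_ap",
    "confusion",
]


@dataclass(frozen=True)
class MatchResult:
    """Greedy matching outcome: index pairs plus unmatched indices."""

    pairs: tuple[tuple[int, int], ...]  # (prediction index, truth index)
    unmatched_preds: tuple[int, ...]  # false positives
    unmatched_truths: tuple[int, ...]  # false negatives

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_preds)

    @property
    def fn(self) -> int:
        return len(self.unmatched_truths)


def match(
    preds: DetectionSet,
    truths: DetectionSet,
    iou_thresh: float = 0.5,
    class_agnostic: bool = False,
) -> MatchResult:
    """Greedily match predictions to truths at an IoU threshold.

    Each truth and each prediction is used at most once.  Ties in IoU break
    toward the lower truth index; prediction order is score-descending with
    the original index as tiebreaker (deterministic).
    """
    if preds.frame != truths.frame:
        raise ValueError(
            f"frame mismatch: predictions {preds.frame!r} vs truths {truths.frame!r}"
        )
    order = sorted(range(len(preds)), key=lambda i: (-preds.boxes[i].score, i))
    claimed = [False] * len(truths)
    pairs: list[tuple[int, int]] = []
    fps: list[int] = []
    for pi in order:
        p = preds.boxes[pi]
        best_j, best_iou = -1, iou_thresh
        for tj, t in enumerate(truths.boxes):
            if claimed[tj]:
                continue
            if not class_agnostic and t.class_id != p.class_id:
                continue
            v = iou(p, t)
            if v > best_iou or (v == best_iou and best_j == -1 and v >= iou_thresh):
                best_j, best_iou = tj, v
        if best_j >= 0:
            claimed[best_j] = True
            pairs.append((pi, best_j))
        else:
            fps.append(pi)
    fns = [j for j, c in enumerate(claimed) if not c]
    return MatchResult(tuple(pairs), tuple(fps), tuple(fns))


def prf1(m: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F1) with the 0/0 -> 0 convention."""
    tp, fp, fn = m.tp, m.fp, m.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _as_pairs(
    preds: DetectionSet | Sequence[DetectionSet],
    truths: DetectionSet | Sequence[DetectionSet],
) -> list[tuple[DetectionSet, DetectionSet]]:
    if isinstance(preds, DetectionSet):
        preds = [preds]
    if isinstance(truths, DetectionSet):
        truths = [truths]
    if len(preds) != len(truths):
        raise ValueError("prediction and truth collections differ in length")
    return list(zip(preds, truths))


def average_precision(
    preds: DetectionSet | Sequence[DetectionSet],
    truths: DetectionSet | Sequence[DetectionSet],
    iou_thresh: float = 0.5,
    class_agnostic: bool = False,
) -> float:
    """Area under the all-point-interpolated PR curve over one or more images."""
    pairs = _as_pairs(preds, truths)
    n_truth = sum(len(t) for _, t in pairs)
    scored: list[tuple[float, bool]] = []
    for p_set, t_set in pairs:
        m = match(p_set, t_set, iou_thresh=iou_thresh, class_agnostic=class_agnostic)
        hit = {pi for pi, _ in m.pairs}
        for i, b in enumerate(p_set.boxes):
            scored.append((b.score, i in hit))
    if n_truth == 0:
        return 0.0
    if not scored:
        return 0.0
    scored.sort(key=lambda t: -t[0])
    flags = np.array([f for _, f in scored], dtype=float)
    cum_tp = np.cumsum(flags)
    recall = cum_tp / n_truth
    precision = cum_tp / np.arange(1, len(flags) + 1)
    # Monotone precision envelope, then sum over recall steps.
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    steps = np.nonzero(np.diff(mrec) > 0)[0]
    return float(np.sum((mrec[steps + 1] - mrec[steps]) * mpre[steps + 1]))


def _filter_class(dets: DetectionSet, class_id: int) -> DetectionSet:
    return dets.with_boxes(b for b in dets.boxes if b.class_id == class_id)


def per_class_ap(
    preds: DetectionSet | Sequence[DetectionSet],
    truths: DetectionSet | Sequence[DetectionSet],
    iou_thresh: float = 0.5,
) -> dict[int, float]:
    """AP per class, for the classes present in the ground truth."""
    pairs = _as_pairs(preds, truths)
    classes = sorted({b.class_id for _, t in pairs for b in t.boxes})
    return {
        c: average_precision(
            [_filter_class(p, c) for p, _ in pairs],
            [_filter_class(t, c) for _, t in pairs],
            iou_thresh=iou_thresh,
        )
        for c in classes
    }


def mean_ap(aps: Mapping[int, float] | Sequence[float]) -> float:
    """Unweighted mean of per-class AP values; 0 for an empty collection."""
    values = list(aps.values()) if isinstance(aps, Mapping) else list(aps)
    return float(np.mean(values)) if values else 0.0


@dataclass(frozen=True)
class ConfusionMatrix:
    """(K+1) x (K+1) counts over K classes plus background (last index).

    Rows are ground truth, columns are predictions.
    """

    counts: np.ndarray
    class_names: tuple[str, ...]

    @property
    def background_index(self) -> int:
        return len(self.class_names)

    def normalized(self) -> np.ndarray:
        """Row-normalised fractions; all-zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def to_dataframe(self, normalized: bool = False) -> pd.DataFrame:
        labels = list(self.class_names) + ["background"]
        data = self.normalized() if normalized else self.counts
        return pd.DataFrame(data, index=labels, columns=labels)


def confusion(
    preds: DetectionSet | Sequence[DetectionSet],
    truths: DetectionSet | Sequence[DetectionSet],
    class_names: Sequence[str],
    iou_thresh: float = 0.5,
    score_thresh: float = 0.25,
) -> ConfusionMatrix:
    """Detection confusion matrix with a background class.

    Predictions below ``score_thresh`` are ignored; spatial matching is
    class-agnostic, so a whitefly predicted as a thrips lands in the
    (whitefly, thrips) cell rather than a miss plus a false alarm.
    """
    k = len(class_names)
    counts = np.zeros((k + 1, k + 1), dtype=int)
    for p_set, t_set in _as_pairs(preds, truths):
        p_kept = p_set.with_boxes(b for b in p_set.boxes if b.score >= score_thresh)
        m = match(p_kept, t_set, iou_thresh=iou_thresh, class_agnostic=True)
        for pi, tj in m.pairs:
            counts[t_set.boxes[tj].class_id, p_kept.boxes[pi].class_id] += 1
        for tj in m.unmatched_truths:
            counts[t_set.boxes[tj].class_id, k] += 1
        for pi in m.unmatched_preds:
            counts[k, p_kept.boxes[pi].class_id] += 1
    return ConfusionMatrix(counts, tuple(class_names))
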