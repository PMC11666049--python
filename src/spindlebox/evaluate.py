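"""Detection evaluation: IoU matching, PR curves, AP and mAP.

The protocol mirrors standard object-detection scoring as applied to EEG
event images: a predicted box counts as a true positive when its
intersection-over-union with an unmatched ground-truth box of the same class
reaches the IoU threshold; matching is greedy in order of descending
confidence with each ground truth usable once.  Precision and recall are
accumulated over the pooled detections of a whole image set,

    recall    = 100% × TP / (number of ground truths),
    precision = 100% × TP / (number of predictions kept so far),

average precision is the area under the precision–recall curve (with the
usual monotone-envelope interpolation; a COCO-style 101-point variant is also
available), and the mean average precision summarises the 2 classes ×
3 IoU-threshold grid {50, 60, 70}%:

    mAP = (1/6) Σ_{j ∈ {0.5, 0.6, 0.7}} Σ_{i ∈ {SS, KC}} AP_ij.

Cross-validated results are aggregated per fold: the fold mean and the
population standard deviation (divisor N), both rounded half-away-from-zero
to one decimal for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np

from .render import BoundingBox
from .signal_io import EventClass

__all__ = [
    "Detection",
    "PRCurve",
    "EvalReport",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_average_precision",
    "evaluate_detections",
    "split_dataset",
    "kfold_split",
    "leave_subject_out_split",
    "aggregate_folds",
    "round_percent",
]

DEFAULT_IOU_THRESHOLDS = (0.5, 0.6, 0.7)


@dataclass(frozen=True)
class Detection:
    """A predicted box with class, confidence and source image."""

    box: BoundingBox
    event_class: EventClass
    confidence: float
    image_id: Hashable

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class PRCurve:
    """Paired recall/precision points, recall non-decreasing, both in [0, 1]."""

    recall: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.recall, dtype=float)
        p = np.asarray(self.precision, dtype=float)
        object.__setattr__(self, "recall", r)
        object.__setattr__(self, "precision", p)
        if r.shape != p.shape or r.ndim != 1:
            raise ValueError("recall and precision must be 1-D of equal length")
        if r.size and (np.any(np.diff(r) < -1e-12) or r.min() < -1e-12 or r.max() > 1 + 1e-12):
            raise ValueError("recall must be sorted ascending within [0, 1]")

    @property
    def empty(self) -> bool:
        return self.recall.size == 0


def round_percent(value: float) -> float:
    """Round a percentage half-away-from-zero to 1 decimal (table style)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area of two half-open pixel boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    # (x_min + width) - x_min can differ from width by an ulp, which would
    # push the ratio of coincident boxes marginally past 1
    return min(inter / union, 1.0)


def match_detections(
    detections: Sequence[Detection],
    ground_truths: Mapping[Hashable, Sequence[BoundingBox]],
    iou_threshold: float,
) -> tuple[list[bool], int]:
    """Greedy one-to-one matching of detections against ground truths.

    Detections (one class at a time) are sorted by descending confidence and
    each is matched to the unmatched ground truth in its image with the
    highest IoU, provided that IoU ≥ *iou_threshold*.  Returns per-detection
    TP flags in that confidence order plus the count of unmatched truths
    (false negatives).

    ``ground_truths`` maps image id → boxes of the class under evaluation;
    detections whose ``image_id`` has no entry are counted as false
    positives.
    """
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].confidence, i),
    )
    matched: dict[Hashable, list[bool]] = {
        img: [False] * len(boxes) for img, boxes in ground_truths.items()
    }
    flags: list[bool] = []
    for i in order:
        det = detections[i]
        boxes = ground_truths.get(det.image_id, ())
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(boxes):
            if matched[det.image_id][j]:
                continue
            v = iou(det.box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[det.image_id][best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    n_truths = sum(len(b) for b in ground_truths.values())
    fn = n_truths - sum(flags)
    return flags, fn


def precision_recall(flags: Sequence[bool], n_truths: int) -> PRCurve:
    """Cumulative precision/recall over detections in confidence order.

    ``recall_k = cumTP_k / n_truths`` and ``precision_k = cumTP_k / k``.
    With no ground truths recall is undefined, so any detections yield the
    empty-curve sentinel.
    """
    if n_truths < 0:
        raise ValueError("n_truths must be >= 0")
    if n_truths == 0 or not flags:
        return PRCurve(np.empty(0), np.empty(0))
    tp = np.cumsum(np.asarray(flags, dtype=float))
    k = np.arange(1, len(flags) + 1, dtype=float)
    return PRCurve(tp / n_truths, tp / k)


def _envelope(recall: np.ndarray, precision: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Monotone precision envelope: p̃(r) = max precision at recall ≥ r."""
    env = np.maximum.accumulate(precision[::-1])[::-1]
    return recall, env


def average_precision(curve: PRCurve, interpolation: str = "all_points") -> float:
    """Area under the PR curve, in percent.

    ``all_points`` integrates the monotone precision envelope over every
    recall step; ``points_101`` averages the enveloped precision sampled at
    recall 0, 0.01, …, 1 (the COCO 2017 primary-metric grid).  An empty
    curve (no detections or no ground truths) scores 0.
    """
    if curve.empty:
        return 0.0
    recall, env = _envelope(curve.recall, curve.precision)
    if interpolation == "all_points":
        r = np.concatenate([[0.0], recall])
        return 100.0 * float(np.sum(np.diff(r) * env))
    if interpolation == "points_101":
        grid = np.linspace(0.0, 1.0, 101)
        # precision at recall ≥ g, zero beyond the last achieved recall
        idx = np.searchsorted(recall, grid, side="left")
        samples = np.where(idx < env.size, env[np.minimum(idx, env.size - 1)], 0.0)
        return 100.0 * float(samples.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_average_precision(ap_table: Mapping) -> float:
    """Unweighted mean of AP cells (percent).

    Accepts either a flat mapping ``{(class, iou): AP}`` or a nested mapping
    ``{class: {iou: AP}}``; in the full protocol the table has the 6 cells
    of 2 classes × IoU {0.5, 0.6, 0.7}.
    """
    values: list[float] = []
    for v in ap_table.values():
        if isinstance(v, Mapping):
            values.extend(float(x) for x in v.values())
        else:
            values.append(float(v))
    if not values:
        raise ValueError("mAP of an empty AP table is undefined")
    return float(np.mean(values))


@dataclass
class EvalReport:
    """AP per class per IoU threshold, mAP, and match counts."""

    ap: dict[EventClass, dict[float, float]]
    map_: float
    counts: dict[EventClass, dict[float, dict[str, int]]]
    interpolation: str = "all_points"

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "AP": {
                cls.value: {f"{t:g}": ap for t, ap in row.items()}
                for cls, row in self.ap.items()
            },
            "mAP": self.map_,
            "counts": {
                cls.value: {f"{t:g}": c for t, c in row.items()}
                for cls, row in self.counts.items()
            },
            "interpolation": self.interpolation,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        """Plain-text table: one row per class × IoU threshold, then mAP."""
        lines = [f"{'IoU':>5}  {'class':<9} {'AP %':>6}  (TP/FP/FN)"]
        for cls, row in self.ap.items():
            for t, ap in row.items():
                c = self.counts[cls][t]
                lines.append(
                    f"{100 * t:>4.0f}%  {cls.value:<9} {round_percent(ap):>6.1f}"
                    f"  ({c['tp']}/{c['fp']}/{c['fn']})"
                )
        lines.append(f"mAP = {round_percent(self.map_):.1f}%")
        return "\n".join(lines)


def evaluate_detections(
    detections: Sequence[Detection],
    ground_truths: Mapping[Hashable, Sequence[BoundingBox]],
    iou_thresholds: Sequence[float] = DEFAULT_IOU_THRESHOLDS,
    interpolation: str = "all_points",
) -> EvalReport:
    """Score detections against ground truths over the class × IoU grid.

    ``ground_truths`` maps image id → all ground-truth boxes of that image
    (any class); detections and truths are paired per class, PR curves are
    pooled over images, and the report carries AP for every cell plus their
    unweighted mean (mAP).
    """
    ap: dict[EventClass, dict[float, float]] = {}
    counts: dict[EventClass, dict[float, dict[str, int]]] = {}
    for cls in EventClass:
        cls_dets = [d for d in detections if d.event_class is cls]
        cls_truths = {
            img: [b for b in boxes if b.event_class is cls]
            for img, boxes in ground_truths.items()
        }
        n_truths = sum(len(b) for b in cls_truths.values())
        ap[cls] = {}
        counts[cls] = {}
        for t in iou_thresholds:
            flags, fn = match_detections(cls_dets, cls_truths, t)
            curve = precision_recall(flags, n_truths)
            ap[cls][t] = average_precision(curve, interpolation)
            counts[cls][t] = {
                "tp": int(sum(flags)),
                "fp": int(len(flags) - sum(flags)),
                "fn": int(fn),
            }
    map_ = mean_average_precision(ap)
    return EvalReport(ap=ap, map_=map_, counts=counts, interpolation=interpolation)


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


def split_dataset(
    n_items: int,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int | None = None,
) -> tuple[np.ndarray, ...]:
    """Random train/val/test index split by fractions (e.g. 50/10/40).

    Fractions must sum to 1; sizes are largest-remainder rounded so the
    partition is exact and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if n_items < len(fractions):
        raise ValueError("need at least one item per split part")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    exact = np.asarray(fractions) * n_items
    sizes = np.floor(exact).astype(int)
    rema = exact - sizes
    for i in np.argsort(-rema)[: n_items - sizes.sum()]:
        sizes[i] += 1
    out, pos = [], 0
    for s in sizes:
        out.append(np.sort(perm[pos : pos + s]))
        pos += s
    return tuple(out)


def kfold_split(
    n_items: int, k: int = 5, seed: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k near-equal folds; each item appears in exactly one test fold."""
    if not 2 <= k <= n_items:
        raise ValueError(f"k must be in [2, n_items], got k={k}, n={n_items}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        out.append((train, test))
    return out


def leave_subject_out_split(
    subject_ids: Sequence[str], seed: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per subject: all of that subject's items form the test set.

    Guarantees no subject contributes to both train and test of any fold —
    the cross-subject generalization protocol.
    """
    ids = np.asarray(subject_ids)
    unique = sorted(set(ids.tolist()))
    if len(unique) < 2:
        raise ValueError("leave-subject-out needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    out = []
    for subject in order:
        test = np.flatnonzero(ids == subject)
        train = np.flatnonzero(ids != subject)
        out.append((train, test))
    return out


def aggregate_folds(fold_values: Sequence[float]) -> tuple[float, float]:
    """Fold mean and population standard deviation (divisor N), rounded to
    1 decimal as reported in cross-validation tables."""
    if not len(fold_values):
        raise ValueError("need at least one fold")
    arr = np.asarray(fold_values, dtype=float)
    return round_percent(float(arr.mean())), round_percent(float(arr.std(ddof=0)))
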