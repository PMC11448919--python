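"""Classification and detection metrics.

Classification metrics are the usual one-vs-rest precision

    P = TP / (TP + FP),

recall

    R = TP / (TP + FN),

and their harmonic mean

    F1 = 2 P R / (P + R),

reported per class with an unweighted macro mean.  Detection quality is
measured by intersection over union (IoU = |A n B| / |A u B|) between
predicted and ground-truth regions (boxes or masks), greedy score-ordered
matching at an IoU threshold, and COCO-style average precision: the area
under the precision-recall curve with 101-point interpolation, averaged over
IoU thresholds 0.50:0.05:0.95, object-size bins and classes to give mAP.

Degenerate conventions (documented, used throughout): precision and recall
are 0 when their denominator is 0; AP is undefined (``None``) when a cell has
no ground truth, and undefined cells are excluded from every mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import InstanceAnnotation
from .geometry import BinaryMask, BoundingBox
from .targeting import DEFAULT_PROBABILITY_THRESHOLD, Detection

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "ClassificationReport",
    "MatchResult",
    "APResult",
    "confusion_counts",
    "precision",
    "recall",
    "f1",
    "classification_report",
    "iou",
    "match_detections",
    "average_precision",
    "mean_ap",
    "detection_as_classification",
    "COCO_THRESHOLDS",
    "SIZE_BINS",
]

#: Standard COCO IoU threshold sweep, 0.50 to 0.95 in steps of 0.05.
COCO_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))

#: Object-size bins by pixel area; boundaries inclusive on the lower bin.
SIZE_BINS: dict[str, tuple[float, float]] = {
    "all": (0.0, float("inf")),
    "small": (0.0, 32.0 * 32.0),
    "medium": (32.0 * 32.0, 96.0 * 96.0),
    "large": (96.0 * 96.0, float("inf")),
}

_RECALL_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest true/false positive/negative counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    truth: Sequence[str], predicted: Sequence[str], positive_class: str
) -> ConfusionCounts:
    """Count one-vs-rest outcomes for ``positive_class``."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} vs {len(predicted)}")
    if len(truth) == 0:
        raise ValueError("label vectors are empty")
    tp = fp = fn = tn = 0
    for t, p in zip(truth, predicted):
        t_pos = t == positive_class
        p_pos = p == positive_class
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and p_pos:
            fp += 1
        elif t_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when no positive predictions were made."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when there are no positive ground truths."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    return 2.0 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class one-vs-rest metrics and their unweighted macro mean.

    A class that occurs in neither the truth nor the predictions is
    *undefined* — reported as ``None`` and excluded from the macro mean.
    """

    per_class: dict[str, ClassMetrics | None]

    @property
    def macro_f1(self) -> float:
        defined = [m.f1 for m in self.per_class.values() if m is not None]
        return float(np.mean(defined))


def classification_report(
    truth: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str],
) -> ClassificationReport:
    """One-vs-rest metrics for every class plus the macro-mean F1."""
    known = set(classes)
    stray = {lab for lab in list(truth) + list(predicted) if lab not in known}
    if stray:
        raise ValueError(f"labels outside the class set: {sorted(stray)}")
    per_class: dict[str, ClassMetrics | None] = {}
    for cls in classes:
        c = confusion_counts(truth, predicted, cls)
        if c.tp + c.fp + c.fn == 0:
            per_class[cls] = None
            continue
        p, r = precision(c), recall(c)
        per_class[cls] = ClassMetrics(precision=p, recall=r, f1=f1(p, r))
    return ClassificationReport(per_class=per_class)


def iou(a: BinaryMask | BoundingBox, b: BinaryMask | BoundingBox) -> float:
    """Intersection over union of two masks or two boxes."""
    if isinstance(a, BinaryMask) and isinstance(b, BinaryMask):
        if a.shape != b.shape:
            raise ValueError("mask dimensions differ")
        inter = int((a.array & b.array).sum())
        union = int((a.array | b.array).sum())
    elif isinstance(a, BoundingBox) and isinstance(b, BoundingBox):
        inter = a.intersection_area(b)
        union = a.area + b.area - inter
    else:
        raise TypeError("iou needs two masks or two boxes")
    if union == 0:
        raise ValueError("IoU is undefined for two empty regions")
    return inter / union


def _det_geometry(d: Detection, geometry: str):
    return d.mask if geometry == "mask" else d.bbox


def _gt_geometry(g: InstanceAnnotation, geometry: str):
    return g.mask if geometry == "mask" else g.bbox


@dataclass(frozen=True)
class MatchResult:
    """Greedy matching outcome for one image at one IoU threshold.

    ``det_is_tp`` aligns with the input detection order; ``gt_matched``
    aligns with the input ground-truth order.  Every ground truth is matched
    at most once.
    """

    iou_threshold: float
    det_is_tp: tuple[bool, ...]
    gt_matched: tuple[bool, ...]


def match_detections(
    ground_truth: Sequence[InstanceAnnotation],
    detections: Sequence[Detection],
    iou_threshold: float,
    geometry: str = "mask",
) -> MatchResult:
    """COCO-style greedy matching within one image.

    Detections are processed in descending probability; each is matched to
    the not-yet-matched same-category ground truth with the highest IoU,
    provided that IoU reaches the threshold.  Unmatched detections are false
    positives.
    """
    if geometry not in ("mask", "box"):
        raise ValueError("geometry must be 'mask' or 'box'")
    order = sorted(
        range(len(detections)), key=lambda i: -detections[i].probability
    )
    gt_matched = [False] * len(ground_truth)
    det_is_tp = [False] * len(detections)
    for i in order:
        det = detections[i]
        best_j = -1
        best_iou = 0.0
        for j, gt in enumerate(ground_truth):
            if gt_matched[j] or gt.category != det.category:
                continue
            val = iou(_det_geometry(det, geometry), _gt_geometry(gt, geometry))
            if val > best_iou:
                best_iou = val
                best_j = j
        if best_j >= 0 and best_iou >= iou_threshold:
            gt_matched[best_j] = True
            det_is_tp[i] = True
    return MatchResult(
        iou_threshold=iou_threshold,
        det_is_tp=tuple(det_is_tp),
        gt_matched=tuple(gt_matched),
    )


def average_precision(
    scored_flags: Iterable[tuple[float, bool]], n_ground_truth: int
) -> float | None:
    """COCO 101-point interpolated average precision.

    ``scored_flags`` pools ``(probability, is_true_positive)`` pairs over all
    images.  Detections are sorted by descending probability, the
    precision-recall curve is accumulated, and AP is the mean of the
    interpolated precision ``max{P(r') : r' >= r}`` over the recall grid
    0, 0.01, ..., 1.  Returns ``None`` (undefined) when there is no ground
    truth.
    """
    if n_ground_truth < 0:
        raise ValueError("n_ground_truth must be >= 0")
    if n_ground_truth == 0:
        return None
    pairs = sorted(scored_flags, key=lambda sf: -sf[0])
    if not pairs:
        return 0.0
    tp_cum = np.cumsum([flag for _, flag in pairs])
    fp_cum = np.cumsum([not flag for _, flag in pairs])
    rec = tp_cum / n_ground_truth
    prec = tp_cum / (tp_cum + fp_cum)
    # running maximum of precision from the high-recall end
    prec_envelope = np.maximum.accumulate(prec[::-1])[::-1]
    idx = np.searchsorted(rec, _RECALL_GRID, side="left")
    interp = np.where(idx < len(rec), prec_envelope[np.minimum(idx, len(rec) - 1)], 0.0)
    return float(interp.mean())


@dataclass(frozen=True)
class APResult:
    """AP per (category, IoU threshold, size bin), with mAP aggregates."""

    ap: dict[tuple[str, float, str], float | None]
    geometry: str

    def mean(
        self,
        categories: Sequence[str] | None = None,
        thresholds: Sequence[float] | None = None,
        size_bin: str = "all",
    ) -> float | None:
        """Mean AP over the selected cells, ignoring undefined ones."""
        vals = [
            v
            for (cat, thr, sb), v in self.ap.items()
            if sb == size_bin
            and (categories is None or cat in categories)
            and (thresholds is None or thr in thresholds)
            and v is not None
        ]
        return float(np.mean(vals)) if vals else None

    @property
    def map_all(self) -> float | None:
        """mAP over all categories and thresholds, size bin 'all'."""
        return self.mean()


def mean_ap(
    ground_truth: Mapping[str, Sequence[InstanceAnnotation]],
    detections: Mapping[str, Sequence[Detection]],
    thresholds: Sequence[float] | None = None,
    size_bins: Mapping[str, tuple[float, float]] | None = None,
    geometry: str = "mask",
) -> APResult:
    """AP per (category, threshold, size bin) over a set of images.

    ``ground_truth`` and ``detections`` map image ids to per-image lists.
    The size bin of a ground-truth object is decided by its mask pixel count
    (mask geometry) or box area (box geometry); detections are binned by
    their own area the same way.  A cell with no ground truth is undefined.
    """
    if thresholds is None:
        thresholds = COCO_THRESHOLDS
    if not thresholds:
        raise ValueError("threshold list is empty")
    if size_bins is None:
        size_bins = SIZE_BINS

    categories = sorted(
        {g.category for gts in ground_truth.values() for g in gts}
        | {d.category for dets in detections.values() for d in dets}
    )
    image_ids = sorted(set(ground_truth) | set(detections))

    def _area(obj, geom: str) -> float:
        region = obj.mask if geom == "mask" else obj.bbox
        return float(region.area)

    ap: dict[tuple[str, float, str], float | None] = {}
    for cat in categories:
        for bin_name, (lo, hi) in size_bins.items():
            def in_bin(obj) -> bool:
                a = _area(obj, geometry)
                return lo < a <= hi or (a == 0 and lo == 0)

            gts_by_img = {
                img: [
                    g
                    for g in ground_truth.get(img, [])
                    if g.category == cat and in_bin(g)
                ]
                for img in image_ids
            }
            dets_by_img = {
                img: [
                    d
                    for d in detections.get(img, [])
                    if d.category == cat and in_bin(d)
                ]
                for img in image_ids
            }
            n_gt = sum(len(v) for v in gts_by_img.values())
            for thr in thresholds:
                if n_gt == 0:
                    ap[(cat, float(thr), bin_name)] = None
                    continue
                pooled: list[tuple[float, bool]] = []
                for img in image_ids:
                    res = match_detections(
                        gts_by_img[img], dets_by_img[img], thr, geometry
                    )
                    pooled.extend(
                        (d.probability, flag)
                        for d, flag in zip(dets_by_img[img], res.det_is_tp)
                    )
                ap[(cat, float(thr), bin_name)] = average_precision(pooled, n_gt)
    return APResult(ap=ap, geometry=geometry)


def detection_as_classification(
    detections_per_image: Mapping[str, Sequence[Detection]],
    min_probability: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> dict[str, str]:
    """Collapse detections to an image-level Crystals / NoCrystals call.

    An image is 'Crystals' iff at least one crystal-category detection
    survives the probability threshold.
    """
    return {
        image_id: (
            "Crystals"
            if any(
                d.category == "crystal" and d.probability >= min_probability
                for d in dets
            )
            else "NoCrystals"
        )
        for image_id, dets in detections_per_image.items()
    }
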