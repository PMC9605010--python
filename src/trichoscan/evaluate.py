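"""Detection and classification evaluation.

Detection quality is scored with the standard instance-detection protocol
over circular regions of interest: exact circle-circle IoU (closed-form lens
area, with a rasterized cross-check variant), greedy score-ordered matching
at an IoU threshold, all-point-interpolated average precision, and mAP
averaged over classes and over the IoU threshold sweep
{0.50, 0.55, ..., 0.95} (mAP(50)/mAP(75) at the single thresholds).

Classification quality uses 3x3 confusion matrices (rows = true class),
one-vs-rest precision/recall/F1, overall accuracy, and the support-weighted
misclassification rate: given per-true-class error fractions and class
supports, ``sum_c support_c * error_c / sum_c support_c`` — the complement
of accuracy when both derive from the same confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from trichoscan.datamodel import CLASS_NAMES, Circle

#: COCO-style IoU threshold sweep for the headline mAP
DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. AP with zero ground truths)."""


# ---------------------------------------------------------------------------
# Circle IoU
# ---------------------------------------------------------------------------


def circle_iou(a: Circle, b: Circle) -> float:
    """Exact intersection-over-union of two circles (closed-form lens area)."""
    d = math.hypot(a.cx - b.cx, a.cy - b.cy)
    ra, rb = a.r, b.r
    if d >= ra + rb:
        return 0.0
    area_a, area_b = math.pi * ra * ra, math.pi * rb * rb
    if d <= abs(ra - rb):
        inter = min(area_a, area_b)
    else:
        # circular-segment (lens) area
        cos_a = (d * d + ra * ra - rb * rb) / (2.0 * d * ra)
        cos_b = (d * d + rb * rb - ra * ra) / (2.0 * d * rb)
        cos_a = min(1.0, max(-1.0, cos_a))
        cos_b = min(1.0, max(-1.0, cos_b))
        t = (-d + ra + rb) * (d + ra - rb) * (d - ra + rb) * (d + ra + rb)
        inter = (
            ra * ra * math.acos(cos_a)
            + rb * rb * math.acos(cos_b)
            - 0.5 * math.sqrt(max(t, 0.0))
        )
    union = area_a + area_b - inter
    return inter / union


def circle_iou_raster(a: Circle, b: Circle, scale: float = 4.0) -> float:
    """Rasterized IoU estimate (pixel-counting at `scale` samples per px).

    Agrees with :func:`circle_iou` to within ~0.01 for radii >= 5 px; used
    as an independent cross-check of the closed form.
    """
    x0 = min(a.cx - a.r, b.cx - b.r) - 1.0
    x1 = max(a.cx + a.r, b.cx + b.r) + 1.0
    y0 = min(a.cy - a.r, b.cy - b.r) - 1.0
    y1 = max(a.cy + a.r, b.cy + b.r) + 1.0
    xs = np.arange(x0, x1, 1.0 / scale) + 0.5 / scale
    ys = np.arange(y0, y1, 1.0 / scale) + 0.5 / scale
    xx, yy = np.meshgrid(xs, ys)
    in_a = (xx - a.cx) ** 2 + (yy - a.cy) ** 2 <= a.r**2
    in_b = (xx - b.cx) ** 2 + (yy - b.cy) ** 2 <= b.r**2
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(in_a & in_b) / union)


# ---------------------------------------------------------------------------
# Matching and average precision
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchResult:
    """Greedy detection<->truth matching for one image (and one class).

    ``pairs`` holds (detection_index, truth_index, iou) triples; indices not
    appearing are false positives / false negatives respectively.
    """

    scores: tuple[float, ...]
    n_truths: int
    pairs: tuple[tuple[int, int, float], ...]
    tau: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.scores) - len(self.pairs)

    @property
    def fn(self) -> int:
        return self.n_truths - len(self.pairs)

    @property
    def matched_detections(self) -> frozenset:
        return frozenset(di for di, _, _ in self.pairs)


def match_detections(
    det_circles: list[Circle],
    det_scores: list[float],
    truth_circles: list[Circle],
    tau: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching in descending score order.

    Each detection claims the highest-IoU not-yet-matched truth, provided
    IoU >= tau.  Inputs are assumed to come from a single image (and a
    single class unless running class-agnostic).
    """
    if len(det_circles) != len(det_scores):
        raise ValueError("det_circles and det_scores must be aligned")
    order = sorted(range(len(det_circles)), key=lambda i: -det_scores[i])
    taken: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for di in order:
        best_iou, best_ti = 0.0, None
        for ti, truth in enumerate(truth_circles):
            if ti in taken:
                continue
            iou = circle_iou(det_circles[di], truth)
            if iou > best_iou:
                best_iou, best_ti = iou, ti
        if best_ti is not None and best_iou >= tau:
            taken.add(best_ti)
            pairs.append((di, best_ti, best_iou))
    return MatchResult(
        scores=tuple(det_scores), n_truths=len(truth_circles), pairs=tuple(pairs), tau=tau
    )


def average_precision(match_results: list[MatchResult]) -> float:
    """All-point-interpolated AP over score-ranked detections.

    Pools detections from all provided matches (typically one per image),
    ranks by score, builds the precision-recall curve and integrates the
    precision envelope.  Raises :class:`UndefinedMetricError` when there are
    no ground truths (distinct from AP = 0, which means truths exist but
    none were found).
    """
    n_truths = sum(m.n_truths for m in match_results)
    if n_truths == 0:
        raise UndefinedMetricError("AP is undefined with zero ground truths")
    flagged: list[tuple[float, bool]] = []
    for m in match_results:
        matched = m.matched_detections
        flagged.extend((s, i in matched) for i, s in enumerate(m.scores))
    if not flagged:
        return 0.0
    flagged.sort(key=lambda t: -t[0])
    tps = np.cumsum([f for _, f in flagged])
    fps = np.cumsum([not f for _, f in flagged])
    recall = tps / n_truths
    precision = tps / (tps + fps)
    # precision envelope (monotone non-increasing from the right)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def mean_ap(
    dets_by_image: dict[str, list],
    ann_set,
    thresholds=DEFAULT_IOU_THRESHOLDS,
    classes=CLASS_NAMES,
) -> dict:
    """COCO-convention mAP summary over classes and IoU thresholds.

    ``dets_by_image`` maps image_id -> list of FollicleDetection (with
    ``predicted_label`` set for per-class evaluation); ``ann_set`` is the
    ground-truth AnnotationSet.  Returns a dict with ``mAP`` (mean over the
    threshold sweep), ``mAP50``/``mAP75``, and per-class APs at tau=0.5.
    Classes without any ground truths are excluded from the means.
    """
    image_ids = ann_set.image_ids

    def class_ap(label: str | None, tau: float) -> float | None:
        matches = []
        for image_id in image_ids:
            dets = [
                d
                for d in dets_by_image.get(image_id, [])
                if label is None or d.predicted_label == label
            ]
            truths = [
                a.circle
                for a in ann_set.by_image(image_id)
                if label is None or a.label == label
            ]
            matches.append(
                match_detections(
                    [d.circle for d in dets], [d.score for d in dets], truths, tau
                )
            )
        try:
            return average_precision(matches)
        except UndefinedMetricError:
            return None

    any_labels = any(
        d.predicted_label is not None for dets in dets_by_image.values() for d in dets
    )
    class_list: list[str | None] = list(classes) if any_labels else [None]

    def mean_over_classes(tau: float) -> float:
        aps = [class_ap(label, tau) for label in class_list]
        defined = [a for a in aps if a is not None]
        if not defined:
            raise UndefinedMetricError("no class has ground truths")
        return float(np.mean(defined))

    per_class_50 = {
        (label or "all"): class_ap(label, 0.5) for label in class_list
    }
    return {
        "mAP": float(np.mean([mean_over_classes(t) for t in thresholds])),
        "mAP50": mean_over_classes(0.5),
        "mAP75": mean_over_classes(0.75),
        "per_class_AP50": per_class_50,
    }


# ---------------------------------------------------------------------------
# Confusion matrix and classification metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 confusion counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_pairs(cls, true_labels, pred_labels, labels=CLASS_NAMES) -> "ConfusionMatrix":
        idx = {label: i for i, label in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true_labels, pred_labels, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(counts=counts, labels=tuple(labels))

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    @property
    def class_support(self) -> dict[str, int]:
        sums = np.asarray(self.counts).sum(axis=1)
        return {label: int(s) for label, s in zip(self.labels, sums)}

    @property
    def row_normalized(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        sums = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, c / sums, 0.0)
        return out

    def per_class_error(self) -> dict[str, float]:
        """Per-true-class misclassification fraction (off-diagonal mass)."""
        rn = self.row_normalized
        return {
            label: float(1.0 - rn[i, i]) if self.class_support[label] else 0.0
            for i, label in enumerate(self.labels)
        }


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """One-vs-rest precision/recall/F1 per class, plus overall accuracy.

    Zero-denominator cells yield 0 and are flagged in ``zero_division``.
    """
    counts = np.asarray(cm.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    col_sums = counts.sum(axis=0)
    row_sums = counts.sum(axis=1)
    per_class = {}
    flags = []
    for i, label in enumerate(cm.labels):
        if col_sums[i] > 0:
            precision = diag[i] / col_sums[i]
        else:
            precision = 0.0
            flags.append(f"{label}:precision")
        if row_sums[i] > 0:
            recall = diag[i] / row_sums[i]
        else:
            recall = 0.0
            flags.append(f"{label}:recall")
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = 0.0
            flags.append(f"{label}:f1")
        per_class[label] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
        }
    return {
        "per_class": per_class,
        "accuracy": float(diag.sum() / counts.sum()),
        "zero_division": flags,
    }


def weighted_misclassification_rate(
    per_class_error: dict[str, float], support: dict[str, int]
) -> float:
    """Support-weighted mean of per-true-class error fractions.

    Equals 1 - accuracy when errors and supports come from the same
    confusion matrix.
    """
    total = sum(support.values())
    if total <= 0:
        raise ValueError("total support must be > 0")
    for label, err in per_class_error.items():
        if not (0.0 <= err <= 1.0):
            raise ValueError(f"error for {label!r} must be in [0, 1], got {err}")
        if support.get(label, 0) < 0:
            raise ValueError(f"support for {label!r} must be >= 0")
    return float(
        sum(support.get(label, 0) * err for label, err in per_class_error.items()) / total
    )


def evaluate_detections(dets_by_image: dict[str, list], ann_set, tau: float = 0.5) -> dict:
    """Full detection + classification evaluation against ground truth.

    Detection: mAP summary (COCO sweep, mAP50/mAP75) plus pooled
    precision/recall at ``tau`` from class-agnostic matching.
    Classification (when detections carry labels): confusion matrix over
    matched pairs, per-class metrics, and an accuracy variant in which
    unmatched ground truths count as errors.
    """
    summary = mean_ap(dets_by_image, ann_set)

    tp = fp = fn = 0
    true_labels: list[str] = []
    pred_labels: list[str] = []
    for image_id in ann_set.image_ids:
        dets = dets_by_image.get(image_id, [])
        anns = ann_set.by_image(image_id)
        m = match_detections(
            [d.circle for d in dets], [d.score for d in dets], [a.circle for a in anns], tau
        )
        tp += m.tp
        fp += m.fp
        fn += m.fn
        for di, ti, _ in m.pairs:
            if dets[di].predicted_label is not None:
                true_labels.append(anns[ti].label)
                pred_labels.append(dets[di].predicted_label)
    summary["detection"] = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "tau": tau,
    }
    if true_labels:
        cm = ConfusionMatrix.from_pairs(true_labels, pred_labels)
        metrics = classification_metrics(cm)
        n_correct = int(np.diag(np.asarray(cm.counts)).sum())
        metrics["accuracy_with_misses"] = n_correct / (cm.total + fn) if cm.total + fn else 0.0
        summary["confusion_matrix"] = cm
        summary["classification"] = metrics
    return summary


def format_metrics_report(cm: ConfusionMatrix, metrics: dict | None = None) -> str:
    """Human-readable per-class metrics table plus the confusion matrix."""
    metrics = metrics or classification_metrics(cm)
    lines = ["class      precision  recall     f1         support"]
    for label in cm.labels:
        m = metrics["per_class"][label]
        lines.append(
            f"{label:<10} {m['precision']:<10.4f} {m['recall']:<10.4f} "
            f"{m['f1']:<10.4f} {cm.class_support[label]}"
        )
    lines.append(f"accuracy   {metrics['accuracy']:.4f}  (n={cm.total})")
    lines.append("")
    lines.append("confusion matrix (rows=true, cols=pred): " + " ".join(cm.labels))
    for label, row in zip(cm.labels, np.asarray(cm.counts)):
        lines.append(f"  {label:<8} " + " ".join(f"{int(v):>6d}" for v in row))
    return "\n".join(lines)


def plot_confusion_matrix(cm: ConfusionMatrix, ax=None, normalized: bool = True):
    """Render the confusion matrix as a normalized-percentage figure."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    data = cm.row_normalized * 100.0 if normalized else np.asarray(cm.counts, float)
    im = ax.imshow(data, cmap="Blues", vmin=0)
    ax.set_xticks(range(len(cm.labels)), cm.labels)
    ax.set_yticks(range(len(cm.labels)), cm.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fmt = "{:.2f}%" if normalized else "{:.0f}"
    for i in range(len(cm.labels)):
        for j in range(len(cm.labels)):
            ax.text(
                j, i, fmt.format(data[i, j]), ha="center", va="center",
                color="white" if data[i, j] > data.max() / 2 else "black", fontsize=8,
            )
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    return ax
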