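"""Follicle instance detection behind a pluggable contract.

The detection *contract* is simple: any detector (including an external
deep instance-segmentation model) produces a list of
:class:`FollicleDetection` — a circle (or mask), a confidence score in
[0, 1] and an optional predicted label — serialized as detections JSON
(``[{image_id, cx, cy, r, score, label?}, ...]``).

This module ships a deterministic classical *reference detector* for
desk-scale work on synthetic or well-contrasted images:

1. grayscale conversion,
2. background flattening (subtraction of a large-kernel Gaussian estimate),
3. dark-region thresholding (follicle disks and hairs are darker than skin),
4. removal of thin hair strokes, morphological regrouping of the remaining
   disk fragments, connected components,
5. per-component area/coverage filtering and circle fitting.

It also provides the per-instance segmentation-mask loss used when training
mask heads: the average binary cross-entropy over an m x m mask grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from trichoscan.datamodel import Circle


@dataclass(frozen=True)
class FollicleDetection:
    """One predicted follicle: circle geometry, confidence, optional label."""

    image_id: str
    circle: Circle
    score: float
    predicted_label: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class DetectorParams:
    """Reference-detector settings (pixel units, 8-bit gray levels).

    background_sigma
        Gaussian sigma of the background illumination estimate.
    dark_threshold
        A pixel is 'dark' when (gray - background) falls below this.
    hair_gray_max
        Gray level below which a dark pixel is treated as hair rather than
        follicle disk (hairs are near-black, disks moderately dark).
    regroup_radius
        Closing radius used to re-join disk fragments that hair strokes cut
        apart; must stay below half the guaranteed inter-disk gap.
    min_area
        Minimum regrouped component area (px^2) kept as a follicle.
    min_coverage
        Minimum fraction of the fitted circle covered by dark pixels.
    """

    background_sigma: float = 40.0
    dark_threshold: float = -30.0
    hair_gray_max: float = 80.0
    regroup_radius: int = 6
    min_area: float = 30.0
    min_coverage: float = 0.55


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    return img


def detect_follicles_reference(
    image: np.ndarray,
    params: DetectorParams | None = None,
    image_id: str = "image",
) -> list[FollicleDetection]:
    """Detect follicles with the classical reference pipeline.

    Deterministic: identical input and params always yield identical output.
    Returns an empty list on a blank image.  The confidence score of each
    detection is the dark-coverage fraction of its fitted circle.
    """
    params = params or DetectorParams()
    gray = _to_gray(image)
    background = ndimage.gaussian_filter(gray, params.background_sigma)
    flat = gray - background
    dark = flat < params.dark_threshold
    if not dark.any():
        return []

    # disk cores: dark but not hair-black; drop the 1-px anti-alias fringe
    # that runs along every hair stroke, then small specks
    core = dark & (gray >= params.hair_gray_max)
    core = ndimage.binary_opening(core, disk(1))
    lab, n = ndimage.label(core)
    if n:
        sizes = ndimage.sum_labels(core, lab, index=np.arange(1, n + 1))
        core &= np.isin(lab, np.nonzero(sizes >= 8)[0] + 1)
    if not core.any():
        return []

    # regroup sectors of one disk that hair strokes cut apart; the closing
    # radius bridges intra-disk gaps (<= max hair thickness) but not the
    # >= 2*regroup_radius gap between neighbouring disks
    pad = params.regroup_radius
    grouped = ndimage.binary_closing(np.pad(core, pad), disk(pad))[pad:-pad, pad:-pad]
    labels, n_comp = ndimage.label(grouped)
    if n_comp == 0:
        return []

    detections: list[FollicleDetection] = []
    h, w = gray.shape
    for comp in range(1, n_comp + 1):
        mask = (labels == comp) & core
        area = int(mask.sum())
        if area < params.min_area:
            continue
        yy, xx = np.nonzero(mask)
        cx, cy = float(xx.mean()), float(yy.mean())
        d = np.hypot(xx - cx, yy - cy)
        # sector pixels reach the true disk rim; a high quantile of the
        # center distance is robust to hair-covered holes in the disk
        r = float(np.quantile(d, 0.98)) + 0.5
        if r <= 1.0:
            continue
        ygrid, xgrid = np.mgrid[
            max(int(cy - r), 0) : min(int(cy + r) + 2, h),
            max(int(cx - r), 0) : min(int(cx + r) + 2, w),
        ]
        inside = (ygrid - cy) ** 2 + (xgrid - cx) ** 2 <= r**2
        n_inside = int(inside.sum())
        if n_inside == 0:
            continue
        coverage = float(dark[ygrid, xgrid][inside].sum() / n_inside)
        if coverage < params.min_coverage:
            continue
        detections.append(
            FollicleDetection(
                image_id=image_id,
                circle=Circle(cx=cx, cy=cy, r=r),
                score=min(coverage, 1.0),
            )
        )
    detections.sort(key=lambda det: (-det.score, det.circle.cx, det.circle.cy))
    return detections


# ---------------------------------------------------------------------------
# Detections JSON interchange
# ---------------------------------------------------------------------------


def write_detections_json(detections: list[FollicleDetection], path) -> None:
    """Serialize detections to the interchange JSON format."""
    rows = []
    for det in detections:
        row = {
            "image_id": det.image_id,
            "cx": det.circle.cx,
            "cy": det.circle.cy,
            "r": det.circle.r,
            "score": det.score,
        }
        if det.predicted_label is not None:
            row["label"] = det.predicted_label
        rows.append(row)
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_detections_json(path) -> list[FollicleDetection]:
    """Read detections JSON produced by this package or an external detector."""
    with open(path) as fh:
        rows = json.load(fh)
    return [
        FollicleDetection(
            image_id=row["image_id"],
            circle=Circle(cx=float(row["cx"]), cy=float(row["cy"]), r=float(row["r"])),
            score=float(row["score"]),
            predicted_label=row.get("label"),
        )
        for row in rows
    ]


# ---------------------------------------------------------------------------
# Mask loss
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskPair:
    """A true binary m x m mask and the predicted probability grid for the
    ground-truth class."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true)
        yp = np.asarray(self.y_pred)
        if yt.shape != yp.shape:
            raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
        if yp.min() < 0.0 or yp.max() > 1.0:
            raise ValueError("predicted mask values must lie in [0, 1]")


def mask_loss(pair: MaskPair, epsilon: float = 1e-7) -> float:
    """Average binary cross-entropy over the mask grid.

    ``-(1/m^2) * sum[y*log(yhat) + (1-y)*log(1-yhat)]`` with predictions
    clipped to ``[epsilon, 1-epsilon]`` (the loss is undefined at exactly
    0/1).  Non-negative; minimized at ``yhat == y``.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    y = np.asarray(pair.y_true, dtype=float)
    p = np.clip(np.asarray(pair.y_pred, dtype=float), epsilon, 1.0 - epsilon)
    bce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(bce.mean())
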