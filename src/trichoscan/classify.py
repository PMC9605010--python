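"""Follicle feature measurement and rule-based three-class labeling.

A follicle's state is determined by three measurements:

* **follicle radius** (px) — the radius of the annotated/detected circle;
* **hair count** — number of distinct hair strands crossing the circle
  boundary;
* **hair thickness** (px) — median medial-axis width of the strands attached
  to the follicle.

The class bands are::

    severe :  r <= 10,        count <= 1,  thickness <= 3
    normal :  10 < r < 20,    count <= 1,  3 < thickness < 6
    healthy:  r >= 20,        count >= 2,  thickness >= 6

Band boundaries are closed on the severe-ward side so that the rule is total
(a boundary case flags *more* severity, the clinically conservative choice).
When the three features disagree, each feature votes for the class whose band
it falls in (a count of <=1 is consistent with both severe and normal and
contributes half a vote to each); the majority wins and ties break toward the
more severe class.  A strict all-criteria mode is available that returns
``"indeterminate"`` instead of voting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from trichoscan.datamodel import Circle

#: severity order, most severe first (used for tie-breaking)
_SEVERITY_ORDER = ("severe", "normal", "healthy")


@dataclass(frozen=True)
class FollicleFeatures:
    """Measured (radius, hair_count, hair_thickness) for one follicle."""

    radius: float
    hair_count: int
    hair_thickness: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.hair_count < 0:
            raise ValueError(f"hair_count must be >= 0, got {self.hair_count}")
        if self.hair_thickness < 0:
            raise ValueError(f"hair_thickness must be >= 0, got {self.hair_thickness}")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with derived width L_width, height L_height and area."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError("bounding box corners out of order")

    @property
    def L_width(self) -> float:
        return self.x2 - self.x1

    @property
    def L_height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.L_width * self.L_height


@dataclass(frozen=True)
class RuleThresholds:
    """Band cut-points for the three-feature labeling rule (pixels)."""

    severe_r_max: float = 10.0
    normal_r_max: float = 20.0
    severe_t_max: float = 3.0
    normal_t_max: float = 6.0
    healthy_count_min: int = 2

    def __post_init__(self) -> None:
        if not self.severe_r_max < self.normal_r_max:
            raise ValueError("severe_r_max must be < normal_r_max")
        if not self.severe_t_max < self.normal_t_max:
            raise ValueError("severe_t_max must be < normal_t_max")


def bbox_from_circle(c: Circle) -> BoundingBox:
    """Tight axis-aligned bounding box of a circle; area is (2r)^2 = 4r^2."""
    return BoundingBox(x1=c.cx - c.r, y1=c.cy - c.r, x2=c.cx + c.r, y2=c.cy + c.r)


def _radius_votes(r: float, th: RuleThresholds) -> dict[str, float]:
    if r <= th.severe_r_max:
        return {"severe": 1.0}
    if r < th.normal_r_max:
        return {"normal": 1.0}
    return {"healthy": 1.0}


def _thickness_votes(t: float, th: RuleThresholds) -> dict[str, float]:
    if t <= th.severe_t_max:
        return {"severe": 1.0}
    if t < th.normal_t_max:
        return {"normal": 1.0}
    return {"healthy": 1.0}


def _count_votes(count: int, th: RuleThresholds) -> dict[str, float]:
    if count >= th.healthy_count_min:
        return {"healthy": 1.0}
    # 0 or 1 hair is consistent with both severe and normal
    return {"severe": 0.5, "normal": 0.5}


def rule_classify(
    f: FollicleFeatures,
    th: RuleThresholds | None = None,
    mode: str = "majority",
) -> str:
    """Classify a follicle as severe / normal / healthy from its features.

    ``mode="majority"`` (default): each feature votes for the class band it
    falls in; majority wins, ties break toward the more severe class.
    ``mode="strict"``: all three features must agree, otherwise
    ``"indeterminate"`` is returned.
    """
    th = th or RuleThresholds()
    votes = {"severe": 0.0, "normal": 0.0, "healthy": 0.0}
    per_feature = [
        _radius_votes(f.radius, th),
        _count_votes(f.hair_count, th),
        _thickness_votes(f.hair_thickness, th),
    ]
    for v in per_feature:
        for label, w in v.items():
            votes[label] += w

    if mode == "strict":
        consistent = [
            label
            for label in _SEVERITY_ORDER
            if all(label in v for v in per_feature)
        ]
        return consistent[0] if len(consistent) == 1 else "indeterminate"
    if mode != "majority":
        raise ValueError(f"unknown mode {mode!r}")

    best = max(votes.values())
    for label in _SEVERITY_ORDER:  # tie -> more severe
        if votes[label] == best:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Feature extraction from a raster
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for strand segmentation and measurement.

    strand_threshold
        Gray level below which a pixel is considered hair (hairs are rendered
        / imaged near-black; the darkened follicle disk stays above this).
    n_ring_samples
        Angular samples on the circle boundary used for hair counting.
    annulus
        Radial band (as multiples of r) on which strand thickness is
        measured; kept inside the follicle disk and away from both the
        near-center merge of multiple strands and the rounded strand tips.
    thickness_stat
        'area' (default): mean medial-axis width estimated as strand area in
        the annulus divided by total strand centerline length through it —
        sub-pixel accurate because pixel area integrates anti-aliased
        coverage.  'median' / 'mean' / 'max': the corresponding statistic of
        2*EDT-1 sampled along the strand skeleton (integer-quantized but
        independent of the strand-count estimate).
    """

    strand_threshold: float = 80.0
    n_ring_samples: int = 1440
    annulus: tuple[float, float] = (0.55, 1.0)
    thickness_stat: str = "area"


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    return img


def _count_boundary_crossings(
    strand: np.ndarray, circle: Circle, n_samples: int
) -> int:
    """Count distinct strand runs intersecting the circle boundary.

    Samples the boundary at ``n_samples`` angles; contiguous runs of
    strand-positive samples (circularly joined) each count as one strand.
    """
    h, w = strand.shape
    theta = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    xs = np.clip(np.round(circle.cx + circle.r * np.cos(theta)).astype(int), 0, w - 1)
    ys = np.clip(np.round(circle.cy + circle.r * np.sin(theta)).astype(int), 0, h - 1)
    hits = strand[ys, xs]
    if not hits.any():
        return 0
    if hits.all():
        return 1
    # rotate so the sequence starts on a gap, then count rising edges
    start = int(np.argmin(hits))
    rolled = np.roll(hits, -start)
    rising = np.count_nonzero(rolled[1:] & ~rolled[:-1]) + int(rolled[0])
    return int(rising)


def extract_features(
    image: np.ndarray,
    circle: Circle,
    config: FeatureConfig | None = None,
) -> FollicleFeatures:
    """Measure (radius, hair count, hair thickness) for one follicle.

    The radius is taken from the detection/annotation circle.  Hair strands
    are segmented as dark pixels (below ``config.strand_threshold``); the
    hair count is the number of distinct strand runs crossing the circle
    boundary, and the thickness is the medial-axis width of the strands
    measured inside a radial annulus (see :class:`FeatureConfig`).
    """
    config = config or FeatureConfig()
    gray = _to_gray(image)
    h, w = gray.shape

    # local window: everything within annulus_out * r + margin of the center
    reach = config.annulus[1] * circle.r + 4
    x0 = max(int(circle.cx - reach), 0)
    y0 = max(int(circle.cy - reach), 0)
    x1 = min(int(math.ceil(circle.cx + reach)) + 1, w)
    y1 = min(int(math.ceil(circle.cy + reach)) + 1, h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("circle lies outside the image")
    window = gray[y0:y1, x0:x1]
    strand = window < config.strand_threshold
    local = Circle(cx=circle.cx - x0, cy=circle.cy - y0, r=circle.r)

    count = _count_boundary_crossings(strand, local, config.n_ring_samples)

    thickness = 0.0
    lo, hi = config.annulus[0] * circle.r, config.annulus[1] * circle.r
    if strand.any() and hi > lo:
        if config.thickness_stat == "area":
            # strands run radially through the annulus, so total centerline
            # length is (number of strands) * (radial span); pixel area of
            # the anti-aliased strokes integrates coverage sub-pixel exactly
            mid = Circle(cx=local.cx, cy=local.cy, r=(lo + hi) / 2.0)
            k = _count_boundary_crossings(strand, mid, config.n_ring_samples)
            if k > 0:
                yy, xx = np.nonzero(strand)
                d = np.hypot(xx - local.cx, yy - local.cy)
                area = float(np.count_nonzero((d >= lo) & (d < hi)))
                thickness = area / (k * (hi - lo))
        else:
            edt = ndimage.distance_transform_edt(strand)
            skel = skeletonize(strand)
            yy, xx = np.nonzero(skel)
            d = np.hypot(xx - local.cx, yy - local.cy)
            sel = (d >= lo) & (d <= hi)
            if sel.any():
                widths = 2.0 * edt[yy[sel], xx[sel]] - 1.0
                stat = {"median": np.median, "mean": np.mean, "max": np.max}[
                    config.thickness_stat
                ]
                thickness = float(max(stat(widths), 0.0))

    return FollicleFeatures(
        radius=float(circle.r), hair_count=count, hair_thickness=thickness
    )


def write_feature_table(rows, path) -> None:
    """Write per-follicle feature rows as a TSV table.

    ``rows`` is an iterable of ``(image_id, circle, features, label)``.
    """
    with open(path, "w") as fh:
        fh.write("image_id\tcx\tcy\tr\thair_count\thair_thickness\tlabel\n")
        for image_id, circle, feats, label in rows:
            fh.write(
                f"{image_id}\t{circle.cx:.2f}\t{circle.cy:.2f}\t{circle.r:.2f}\t"
                f"{feats.hair_count}\t{feats.hair_thickness:.2f}\t{label}\n"
            )
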