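"""Synthetic scalp-microscopy image generation with exact ground truth.

Emulates the data regime of a 200x trichoscopy study: 640x480 RGB images of
skin with 10-45 annotated hair follicles each, three follicle classes with
disjoint (radius, hair count, hair thickness) bands, and a class mixture
proportional to severe : normal : healthy = 3836 : 11262 : 8914.

A follicle is rendered as a softly darkened disk; its hairs are near-black
anti-aliased strokes (gentle quadratic arcs) of the prescribed thickness
emanating from the follicle center and crossing the circle boundary.  The
background is a skin tone with low-frequency mottle and mild pixel noise.

Placement keeps follicles strictly non-overlapping: the pairwise center
distance is at least ``max(reach_i + r_j, reach_j + r_i, r_i + r_j + 12) + 4``
where ``reach = 1.5 r + 8`` bounds how far a hair can extend from its
follicle center.  This guarantees that no hair strand enters another
follicle's measurement region, so the rendered ground truth is exact for
feature extraction, and that neighbouring disks keep a clear gap for the
reference detector.  Occlusion/overlap scenarios can be produced by relaxing
``SimConfig.non_overlapping``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from trichoscan.datamodel import (
    AnnotationSet,
    Circle,
    CLASS_NAMES,
    FollicleAnnotation,
    write_via_annotations,
)

#: Table-derived default class mixture (severe, normal, healthy).
DEFAULT_MIXTURE_COUNTS = (3836, 11262, 8914)


class PlacementError(RuntimeError):
    """Raised when follicles cannot be placed under the overlap policy."""


# Strict class bands: (r_lo, r_hi), counts, (t_lo, t_hi).  Open boundaries of
# the defining bands (e.g. normal thickness in (3, 6)) carry a rasterization
# guard: 0.5 px on radius and 0.75 px on thickness (half-pixel grid
# quantization plus the anti-alias threshold offset), since sub-pixel
# differences at a band edge are not renderable.  Closed boundaries are kept.
_BANDS: dict[str, dict] = {
    "severe": {"r": (4.0, 10.0), "counts": (1,), "t": (1.5, 3.0)},
    "normal": {"r": (10.5, 19.5), "counts": (1,), "t": (3.75, 5.25)},
    "healthy": {"r": (20.5, 32.0), "counts": (2, 3), "t": (6.75, 10.0)},
}

#: Minimum angular separation between hairs of one follicle (radians).
_MIN_HAIR_SEP = math.radians(75.0)


@dataclass(frozen=True)
class SimFollicle:
    """One simulated follicle: geometry, class label, and hair strokes."""

    circle: Circle
    label: str
    hair_count: int
    hair_thickness: float
    hair_angles: tuple[float, ...]
    hair_lengths: tuple[float, ...]
    hair_curvatures: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.label not in CLASS_NAMES:
            raise ValueError(f"unknown label {self.label!r}")
        if not (
            len(self.hair_angles) == len(self.hair_lengths) == len(self.hair_curvatures) == self.hair_count
        ):
            raise ValueError("hair attribute lengths must equal hair_count")

    @property
    def reach(self) -> float:
        """Upper bound on how far hair pixels extend from the center."""
        return 1.5 * self.circle.r + 8.0

    def at(self, cx: float, cy: float) -> "SimFollicle":
        return replace(self, circle=Circle(cx=cx, cy=cy, r=self.circle.r))


@dataclass
class SimConfig:
    """Study-regime simulation parameters.

    Defaults mirror the targeted imaging regime: 640x480 px images, 10-45 follicles
    per image, class mixture proportional to 3836:11262:8914.
    """

    image_size: tuple[int, int] = (640, 480)  # (width, height)
    follicles_per_image: tuple[int, int] = (10, 45)
    class_mixture: tuple[float, float, float] = DEFAULT_MIXTURE_COUNTS
    background_tone: tuple[int, int, int] = (210, 180, 160)
    mottle_amplitude: float = 0.10
    mottle_sigma: float = 60.0
    pixel_noise: float = 2.0
    hair_gray: tuple[int, int, int] = (25, 21, 19)
    disk_darken: float = 0.36
    disk_edge: float = 2.0
    strict_bands: bool = True
    non_overlapping: bool = True
    max_place_attempts: int = 3000
    max_image_retries: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.follicles_per_image
        if not (1 <= lo <= hi):
            raise ValueError("follicles_per_image range must satisfy 1 <= lo <= hi")
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.min() < 0 or mix.sum() <= 0:
            raise ValueError("class_mixture must be non-negative and sum > 0")

    @property
    def mixture_probs(self) -> np.ndarray:
        mix = np.asarray(self.class_mixture, dtype=float)
        return mix / mix.sum()


def sample_follicle(label: str, config: SimConfig, rng: np.random.Generator) -> SimFollicle:
    """Sample one follicle of the given class (center at the origin).

    With ``strict_bands`` on, the (radius, hair count, thickness) triple is
    drawn strictly inside the class band so the generating label is the
    unique rule-consistent label.
    """
    band = _BANDS[label]
    r_lo, r_hi = band["r"]
    t_lo, t_hi = band["t"]
    if not config.strict_bands:
        # widen by one px on each side, allowing ambiguous boundary cases
        r_lo, r_hi = max(r_lo - 1.0, 2.0), r_hi + 1.0
        t_lo, t_hi = max(t_lo - 1.0, 1.0), t_hi + 1.0
    r = float(rng.uniform(r_lo, r_hi))
    thickness = float(rng.uniform(t_lo, t_hi))
    count = int(rng.choice(band["counts"]))

    angles: list[float] = []
    while len(angles) < count:
        cand = float(rng.uniform(0.0, 2.0 * math.pi))
        if all(
            min(abs(cand - a), 2.0 * math.pi - abs(cand - a)) >= _MIN_HAIR_SEP
            for a in angles
        ):
            angles.append(cand)
    lengths = [float(rng.uniform(1.15 * r, 1.5 * r)) for _ in range(count)]
    curvatures = [float(rng.uniform(-0.06, 0.06)) for _ in range(count)]
    return SimFollicle(
        circle=Circle(cx=0.0, cy=0.0, r=r),
        label=label,
        hair_count=count,
        hair_thickness=thickness,
        hair_angles=tuple(angles),
        hair_lengths=tuple(lengths),
        hair_curvatures=tuple(curvatures),
    )


def _pair_min_distance(a: SimFollicle, b: SimFollicle) -> float:
    ra, rb = a.circle.r, b.circle.r
    return max(a.reach + rb, b.reach + ra, ra + rb + 12.0) + 4.0


def place_follicles(
    follicles: list[SimFollicle], config: SimConfig, rng: np.random.Generator
) -> list[SimFollicle]:
    """Assign centers by rejection sampling under the overlap policy.

    Larger follicles are placed first (better packing); the returned list is
    in placement order.  Raises :class:`PlacementError` when the canvas
    cannot host the requested follicles.
    """
    w, h = config.image_size
    ordered = sorted(follicles, key=lambda f: -f.circle.r)
    placed: list[SimFollicle] = []
    for fol in ordered:
        margin = fol.circle.r + 3.0
        if w - 2 * margin <= 0 or h - 2 * margin <= 0:
            raise PlacementError(f"canvas {w}x{h} too small for radius {fol.circle.r:.1f}")
        for _ in range(config.max_place_attempts):
            cx = float(rng.uniform(margin, w - margin))
            cy = float(rng.uniform(margin, h - margin))
            cand = fol.at(cx, cy)
            if not config.non_overlapping or all(
                math.hypot(cx - p.circle.cx, cy - p.circle.cy) >= _pair_min_distance(cand, p)
                for p in placed
            ):
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place follicle {len(placed) + 1}/{len(ordered)} "
                f"on {w}x{h} canvas under the overlap policy"
            )
    return placed


def sample_image_follicles(config: SimConfig, rng: np.random.Generator) -> list[SimFollicle]:
    """Sample a full image's worth of placed follicles.

    Draws the follicle count uniformly from the configured range and labels
    from the class mixture; on placement exhaustion the whole image is
    redrawn (count and classes included) up to ``max_image_retries`` times.
    """
    lo, hi = config.follicles_per_image
    for _ in range(config.max_image_retries):
        n = int(rng.integers(lo, hi + 1))
        labels = rng.choice(len(CLASS_NAMES), size=n, p=config.mixture_probs)
        follicles = [sample_follicle(CLASS_NAMES[i], config, rng) for i in labels]
        try:
            return place_follicles(follicles, config, rng)
        except PlacementError:
            continue
    raise PlacementError(
        f"no placeable configuration found in {config.max_image_retries} redraws"
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _composite_stroke(
    canvas: np.ndarray,
    center: tuple[float, float],
    angle: float,
    length: float,
    curvature: float,
    thickness: float,
    color: np.ndarray,
) -> None:
    """Paint one anti-aliased hair stroke (quadratic arc) onto the canvas."""
    h, w = canvas.shape[:2]
    cx, cy = center
    dx, dy = math.cos(angle), math.sin(angle)
    p0 = np.array([cx, cy])
    p2 = p0 + length * np.array([dx, dy])
    # control point: chord midpoint offset perpendicular by curvature*length
    perp = np.array([-dy, dx])
    p1 = (p0 + p2) / 2.0 + curvature * length * perp
    pts = _bezier_points(p0, p1, p2, max(int(2 * length), 8))

    pad = thickness / 2.0 + 2.0
    x0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
    x1 = min(int(np.ceil(pts[:, 0].max() + pad)) + 1, w)
    y0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
    y1 = min(int(np.ceil(pts[:, 1].max() + pad)) + 1, h)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    # distance from each pixel center to the sampled arc polyline
    d = np.sqrt(((pix[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    alpha = np.clip(thickness / 2.0 + 0.5 - d, 0.0, 1.0).reshape(yy.shape)
    region = canvas[y0:y1, x0:x1]
    region[:] = region * (1.0 - alpha[..., None]) + color[None, None, :] * alpha[..., None]


def render_scalp_image(
    follicles: list[SimFollicle],
    config: SimConfig,
    rng: np.random.Generator,
    image_id: str = "sim_000",
) -> tuple[np.ndarray, AnnotationSet]:
    """Render placed follicles onto a mottled skin background.

    Returns an 8-bit RGB raster and the exact ground-truth annotation set.
    """
    w, h = config.image_size
    base = np.asarray(config.background_tone, dtype=float)

    canvas = np.broadcast_to(base, (h, w, 3)).astype(float).copy()
    if config.mottle_amplitude > 0:
        field_ = gaussian_filter(rng.standard_normal((h, w)), config.mottle_sigma)
        peak = np.abs(field_).max()
        if peak > 0:
            canvas *= (1.0 + config.mottle_amplitude * field_ / peak)[..., None]
    if config.pixel_noise > 0:
        canvas += rng.normal(0.0, config.pixel_noise, (h, w))[..., None]

    # darkened soft-edged disks
    for fol in follicles:
        c = fol.circle
        pad = c.r + config.disk_edge + 1
        x0, x1 = max(int(c.cx - pad), 0), min(int(c.cx + pad) + 2, w)
        y0, y1 = max(int(c.cy - pad), 0), min(int(c.cy + pad) + 2, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - c.cx, yy - c.cy)
        alpha = np.clip(0.5 + (c.r - d) / config.disk_edge, 0.0, 1.0)
        region = canvas[y0:y1, x0:x1]
        region[:] = region * (1.0 - config.disk_darken * alpha[..., None])

    # hair strokes on top
    hair_color = np.asarray(config.hair_gray, dtype=float)
    for fol in follicles:
        for angle, length, curv in zip(
            fol.hair_angles, fol.hair_lengths, fol.hair_curvatures
        ):
            _composite_stroke(
                canvas,
                (fol.circle.cx, fol.circle.cy),
                angle,
                length,
                curv,
                fol.hair_thickness,
                hair_color,
            )

    raster = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    ann_set = AnnotationSet(
        images=[(image_id, w, h)],
        annotations=[
            FollicleAnnotation(image_id=image_id, circle=f.circle, label=f.label)
            for f in follicles
        ],
    )
    return raster, ann_set


def generate_dataset(
    n_images: int, config: SimConfig | None = None
) -> tuple[dict[str, np.ndarray], AnnotationSet, dict]:
    """Generate a deterministic synthetic dataset.

    Returns ``(images, annotations, manifest)`` where ``images`` maps
    image_id -> uint8 RGB raster and the manifest records per-class totals
    and all sampling parameters.  Identical ``(n_images, config)`` always
    produce byte-identical rasters.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    config = config or SimConfig()
    images: dict[str, np.ndarray] = {}
    all_images: list[tuple[str, int, int]] = []
    all_anns: list[FollicleAnnotation] = []
    for k in range(n_images):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(k,)))
        image_id = f"sim_{k:04d}.png"
        follicles = sample_image_follicles(config, rng)
        raster, ann_set = render_scalp_image(follicles, config, rng, image_id=image_id)
        images[image_id] = raster
        all_images.extend(ann_set.images)
        all_anns.extend(ann_set.annotations)
    ann_set = AnnotationSet(images=all_images, annotations=all_anns)
    counts = ann_set.class_counts()
    manifest = {
        "n_images": n_images,
        "seed": config.seed,
        "image_size": list(config.image_size),
        "follicles_per_image": list(config.follicles_per_image),
        "class_mixture": [float(x) for x in config.mixture_probs],
        "strict_bands": config.strict_bands,
        "non_overlapping": config.non_overlapping,
        "total_annotations": len(ann_set.annotations),
        **{f"n_{name}": counts[name] for name in CLASS_NAMES},
    }
    return images, ann_set, manifest


def save_dataset(
    images: dict[str, np.ndarray], ann_set: AnnotationSet, manifest: dict, out_dir
) -> None:
    """Write PNGs, VIA ground truth, and a key-value manifest to ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for image_id, raster in images.items():
        Image.fromarray(raster).save(out / image_id)
    write_via_annotations(ann_set, out / "annotations.json")
    with open(out / "manifest.txt", "w") as fh:
        for key, value in manifest.items():
            fh.write(f"{key}: {value}\n")
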