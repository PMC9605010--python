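"""Core domain types, VIA-JSON annotation I/O, and dataset splitting.

Coordinates are 0-based continuous pixel coordinates, x rightward and
y downward, matching the VGG Image Annotator (VIA) convention.  A follicle
annotation is a circle ``(cx, cy, r)`` plus a class label; the class-code
convention is fixed::

    0 = severe, 1 = normal, 2 = healthy

Circles extending past the image border are kept unclipped but flagged
(``FollicleAnnotation.out_of_bounds``); area computations always use the
unclipped circle.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Fixed class-code <-> label bijection (0=severe, 1=normal, 2=healthy).
CODE_TO_LABEL: dict[int, str] = {0: "severe", 1: "normal", 2: "healthy"}
LABEL_TO_CODE: dict[str, int] = {v: k for k, v in CODE_TO_LABEL.items()}
#: Class names ordered by code.
CLASS_NAMES: tuple[str, ...] = ("severe", "normal", "healthy")


class ViaParseError(ValueError):
    """Raised when a VIA JSON file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates (cx rightward, cy downward, radius r)."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cx) and math.isfinite(self.cy)):
            raise ValueError(f"circle center must be finite, got ({self.cx}, {self.cy})")
        if not (math.isfinite(self.r) and self.r > 0):
            raise ValueError(f"circle radius must be finite and > 0, got {self.r}")

    @property
    def area(self) -> float:
        return math.pi * self.r**2

    def contains(self, x: float, y: float) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2

    def inside_image(self, width: float, height: float) -> bool:
        """True if the full disk lies within a width x height canvas."""
        return (
            self.cx - self.r >= 0
            and self.cy - self.r >= 0
            and self.cx + self.r <= width
            and self.cy + self.r <= height
        )


@dataclass(frozen=True)
class FollicleAnnotation:
    """One ground-truth follicle: circle geometry + class label + provenance."""

    image_id: str
    circle: Circle
    label: str
    out_of_bounds: bool = False

    def __post_init__(self) -> None:
        if self.label not in LABEL_TO_CODE:
            raise ValueError(
                f"label must be one of {CLASS_NAMES}, got {self.label!r}"
            )

    @property
    def class_code(self) -> int:
        return LABEL_TO_CODE[self.label]


@dataclass
class AnnotationSet:
    """A collection of images and their follicle annotations.

    Parameters
    ----------
    images
        List of ``(image_id, width, height)`` tuples.
    annotations
        Follicle annotations; every ``image_id`` must appear in ``images``.
    metadata
        Free-form provenance, e.g. parse/skip counters from the VIA reader.
    """

    images: list[tuple[str, int, int]]
    annotations: list[FollicleAnnotation]
    metadata: dict = field(default_factory=dict)

    #: sanity bound on per-image annotation count (study regime is 10-45)
    max_per_image: int = 200

    def __post_init__(self) -> None:
        ids = {im[0] for im in self.images}
        if len(ids) != len(self.images):
            raise ValueError("duplicate image_id in images")
        counts: dict[str, int] = {}
        for ann in self.annotations:
            if ann.image_id not in ids:
                raise ValueError(
                    f"annotation references unknown image_id {ann.image_id!r}"
                )
            counts[ann.image_id] = counts.get(ann.image_id, 0) + 1
        for image_id, n in counts.items():
            if n > self.max_per_image:
                raise ValueError(
                    f"image {image_id!r} has {n} annotations "
                    f"(> max_per_image={self.max_per_image})"
                )

    @property
    def image_ids(self) -> list[str]:
        return [im[0] for im in self.images]

    def by_image(self, image_id: str) -> list[FollicleAnnotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CLASS_NAMES}
        for ann in self.annotations:
            counts[ann.label] += 1
        return counts

    def subset(self, image_ids: list[str]) -> "AnnotationSet":
        keep = set(image_ids)
        return AnnotationSet(
            images=[im for im in self.images if im[0] in keep],
            annotations=[a for a in self.annotations if a.image_id in keep],
            metadata=dict(self.metadata),
            max_per_image=self.max_per_image,
        )


@dataclass(frozen=True)
class DatasetSplit:
    """A by-image train/test partition; |train| = round(fraction * N)."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# VIA (VGG Image Annotator) v2 JSON dialect
# ---------------------------------------------------------------------------

_CLASS_ATTR = "class"


def _normalize_code(raw, where: str) -> int:
    """Accept class codes as int or string; reject anything outside {0,1,2}."""
    try:
        code = int(raw)
    except (TypeError, ValueError):
        raise ViaParseError(f"{where}: class code {raw!r} is not an integer")
    if code not in CODE_TO_LABEL:
        raise ViaParseError(f"{where}: class code {code} outside {{0,1,2}}")
    return code


def read_via_annotations(path) -> AnnotationSet:
    """Read a VIA project/export JSON file into an :class:`AnnotationSet`.

    Only circle regions are parsed; regions of any other shape are skipped
    with a logged warning.  The class code is read from the region attribute
    ``"class"`` and may be a string or an integer.  Parse statistics are
    returned in ``AnnotationSet.metadata`` under ``"parsed"``/``"skipped"``.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ViaParseError(f"{path}: malformed JSON: {exc}") from exc

    # VIA exports are either {"_via_img_metadata": {...}} or the bare mapping
    img_meta = doc.get("_via_img_metadata", doc)
    if not isinstance(img_meta, dict):
        raise ViaParseError(f"{path}: expected a VIA image-metadata mapping")

    images: list[tuple[str, int, int]] = []
    annotations: list[FollicleAnnotation] = []
    skipped = 0
    for key, entry in img_meta.items():
        if not isinstance(entry, dict) or "regions" not in entry:
            raise ViaParseError(f"{path}: image entry {key!r} has no regions")
        image_id = entry.get("filename", key)
        width = int(entry.get("width", 0))
        height = int(entry.get("height", 0))
        images.append((image_id, width, height))
        for idx, region in enumerate(entry.get("regions", [])):
            shape = region.get("shape_attributes", {})
            where = f"{image_id} region {idx}"
            if shape.get("name") != "circle":
                logger.warning("%s: skipping non-circle region (%s)", where, shape.get("name"))
                skipped += 1
                continue
            circle = Circle(
                cx=float(shape["cx"]), cy=float(shape["cy"]), r=float(shape["r"])
            )
            code = _normalize_code(
                region.get("region_attributes", {}).get(_CLASS_ATTR), where
            )
            oob = bool(width and height) and not circle.inside_image(width, height)
            annotations.append(
                FollicleAnnotation(
                    image_id=image_id,
                    circle=circle,
                    label=CODE_TO_LABEL[code],
                    out_of_bounds=oob,
                )
            )
    return AnnotationSet(
        images=images,
        annotations=annotations,
        metadata={"parsed": len(annotations), "skipped": skipped, "source": str(path)},
    )


def write_via_annotations(ann_set: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` as VIA v2 JSON readable by VIA and by
    :func:`read_via_annotations`.

    Keys are emitted in sorted canonical order so write -> read -> write is
    byte-identical; class codes are always written as strings.
    """
    img_meta = {}
    by_image: dict[str, list[FollicleAnnotation]] = {im[0]: [] for im in ann_set.images}
    for ann in ann_set.annotations:
        by_image[ann.image_id].append(ann)
    for image_id, width, height in ann_set.images:
        regions = [
            {
                "shape_attributes": {
                    "name": "circle",
                    "cx": float(ann.circle.cx),
                    "cy": float(ann.circle.cy),
                    "r": float(ann.circle.r),
                },
                "region_attributes": {_CLASS_ATTR: str(ann.class_code)},
            }
            for ann in by_image[image_id]
        ]
        img_meta[image_id] = {
            "filename": image_id,
            "width": width,
            "height": height,
            "regions": regions,
        }
    doc = {"_via_img_metadata": img_meta}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def split_dataset(ann_set: AnnotationSet, fraction: float = 0.75, seed: int = 0) -> DatasetSplit:
    """Randomly split images into train/test by image id.

    ``|train| = round(fraction * N)`` (banker's rounding is avoided: standard
    half-up via floor(x+0.5)); annotations travel with their images.  The
    split ignores any regional context, matching a plain random partition of
    the image list.
    """
    n = len(ann_set.images)
    if n < 2:
        raise ValueError(f"need at least 2 images to split, got {n}")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(math.floor(fraction * n + 0.5))  # half-up, not banker's
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    ids = ann_set.image_ids
    train_ids = tuple(sorted(ids[i] for i in order[:n_train]))
    test_ids = tuple(sorted(ids[i] for i in order[n_train:]))
    return DatasetSplit(train_ids=train_ids, test_ids=test_ids, fraction=fraction, seed=seed)


def rescale_annotation(ann: FollicleAnnotation, sx: float, sy: float) -> FollicleAnnotation:
    """Scale a circle annotation by (sx, sy); r scales by sqrt(sx*sy)."""
    c = ann.circle
    return replace(
        ann,
        circle=Circle(cx=c.cx * sx, cy=c.cy * sy, r=c.r * math.sqrt(sx * sy)),
    )
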