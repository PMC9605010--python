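"""Deterministic resizing with annotation rescaling, and augmentation.

All images in the target regime are normalized to 640x480 px, with circle
annotations rescaled by the same factors: cx by ``sx = target_w / in_w``,
cy by ``sy``, and r by the geometric mean ``sqrt(sx * sy)`` (a circle cannot
remain a circle under anisotropic scaling; the geometric mean preserves its
area ratio).  A warning is logged when sx != sy.

The augmentation set mirrors what microscopy capture pipelines need:
brightness/contrast adjustment, horizontal/vertical flips (camera-angle
correction) and Gaussian blur.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from trichoscan.datamodel import AnnotationSet, rescale_annotation

logger = logging.getLogger(__name__)


def resize_with_annotations(
    image: np.ndarray,
    anns: AnnotationSet | None = None,
    target: tuple[int, int] = (640, 480),
) -> tuple[np.ndarray, AnnotationSet | None]:
    """Resize a raster to ``target=(width, height)`` and rescale annotations.

    Bilinear interpolation; a no-op (identity, annotations untouched) when
    the raster is already at the target size.
    """
    arr = np.asarray(image)
    if arr.ndim not in (2, 3) or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError(f"invalid image shape {arr.shape}")
    in_h, in_w = arr.shape[:2]
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError(f"invalid target size {target}")
    sx, sy = tw / in_w, th / in_h
    if (in_w, in_h) == (tw, th):
        return arr, anns
    if not math.isclose(sx, sy):
        logger.info(
            "anisotropic resize (sx=%.4f, sy=%.4f): radii scale by sqrt(sx*sy)", sx, sy
        )
    resized = np.asarray(
        Image.fromarray(arr).resize((tw, th), resample=Image.BILINEAR)
    )
    out_anns = None
    if anns is not None:
        out_anns = AnnotationSet(
            images=[(im[0], tw, th) for im in anns.images],
            annotations=[rescale_annotation(a, sx, sy) for a in anns.annotations],
            metadata=dict(anns.metadata),
        )
    return resized, out_anns


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _brightness(img: np.ndarray, rng, delta: float) -> np.ndarray:
    return img + float(delta)


def _contrast(img: np.ndarray, rng, gain: float) -> np.ndarray:
    return (img - 127.5) * float(gain) + 127.5


def _hflip(img: np.ndarray, rng) -> np.ndarray:
    return img[:, ::-1]


def _vflip(img: np.ndarray, rng) -> np.ndarray:
    return img[::-1, :]


def _gaussian_blur(img: np.ndarray, rng, sigma: float) -> np.ndarray:
    if img.ndim == 3:
        return gaussian_filter(img, (float(sigma), float(sigma), 0), mode="reflect")
    return gaussian_filter(img, float(sigma), mode="reflect")


_AUGMENTATIONS = {
    "brightness": _brightness,
    "contrast": _contrast,
    "hflip": _hflip,
    "vflip": _vflip,
    "gaussian_blur": _gaussian_blur,
}


def augment(image: np.ndarray, spec: list, seed: int = 0) -> np.ndarray:
    """Apply an ordered augmentation pipeline to a raster.

    ``spec`` is a list of operations, each either a name (``"hflip"``) or a
    ``(name, *args)`` tuple / ``[name, *args]`` list, drawn from
    ``brightness(delta)``, ``contrast(gain)``, ``hflip``, ``vflip`` and
    ``gaussian_blur(sigma)``.  Output dtype matches the input; uint8 input
    is clipped back to [0, 255].  Deterministic under ``seed``.
    """
    arr = np.asarray(image)
    out = arr.astype(float)
    rng = np.random.default_rng(seed)
    for op in spec:
        if isinstance(op, str):
            name, args = op, ()
        else:
            name, *args = op
        if name not in _AUGMENTATIONS:
            raise ValueError(
                f"unknown augmentation {name!r}; valid: {sorted(_AUGMENTATIONS)}"
            )
        out = _AUGMENTATIONS[name](out, rng, *args)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        out = np.clip(np.round(out), info.min, info.max).astype(arr.dtype)
    return out
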