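"""12-region scalp assembly and severity heatmap rendering.

The top view of the scalp is modeled as an ellipse divided into a 3 x 4
scheme: three columns (left, center, right) each divided into four regions
from anterior to posterior.  Regions are named ``L1..L4``, ``C1..C4``,
``R1..R4`` (1 = anterior) and carry normalized (u, v) center coordinates
inside the unit ellipse (u rightward, v anterior -> posterior).

``assemble_scalp_map`` combines exactly 12 regional severity results into a
scalp-level estimate Pavg; ``render_heatmap`` paints them on an
ellipse-masked top view with a perceptually ordered colormap (low P = red =
severe, high P = green = healthy by default), smooth Gaussian-weighted
interpolation between region centers (or nearest-region blocks), a color bar
and the Pavg value in the margin.  Rendering is a pure function of the map
and deterministic, so repeated renders are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw

from trichoscan.severity import LocalSeverityResult, average_severity

_COLUMNS = {"L": -0.45, "C": 0.0, "R": 0.45}
_ROWS = {1: -0.6, 2: -0.2, 3: 0.2, 4: 0.6}


def default_region_coords() -> dict[str, tuple[float, float]]:
    """The 12 named region centers on the unit ellipse (u, v)."""
    return {
        f"{col}{row}": (u, v)
        for col, u in _COLUMNS.items()
        for row, v in _ROWS.items()
    }


@dataclass(frozen=True)
class ScalpLayout:
    """Named region centers; exactly 12, all inside the unit ellipse."""

    regions: dict = field(default_factory=default_region_coords)

    def __post_init__(self) -> None:
        if len(self.regions) != 12:
            raise ValueError(f"layout must have exactly 12 regions, got {len(self.regions)}")
        for name, (u, v) in self.regions.items():
            if u * u + v * v > 1.0:
                raise ValueError(f"region {name!r} center ({u}, {v}) outside unit ellipse")

    @property
    def names(self) -> list[str]:
        return list(self.regions)


@dataclass(frozen=True)
class ScalpSeverityMap:
    """12 regional severity results and their scalp-level mean Pavg."""

    layout: ScalpLayout
    results: dict  # region name -> LocalSeverityResult
    Pavg: float

    @property
    def P_values(self) -> dict[str, float]:
        return {name: self.results[name].P for name in self.layout.names}


def assemble_scalp_map(
    results: dict[str, LocalSeverityResult], layout: ScalpLayout | None = None
) -> ScalpSeverityMap:
    """Combine per-region severity results into a scalp severity map.

    ``results`` must contain exactly the 12 layout regions, each once;
    missing or unexpected regions raise an error naming them.
    """
    layout = layout or ScalpLayout()
    expected = set(layout.names)
    got = set(results)
    missing = sorted(expected - got)
    extra = sorted(got - expected)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing regions: {missing}")
        if extra:
            parts.append(f"unexpected regions: {extra}")
        raise ValueError("; ".join(parts))
    pavg = average_severity([results[name].P for name in layout.names])
    return ScalpSeverityMap(layout=layout, results=dict(results), Pavg=pavg)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeatmapOptions:
    """Rendering knobs for the scalp heatmap raster."""

    size: tuple[int, int] = (560, 440)  # (width, height) incl. margin
    margin: int = 110  # right margin for color bar + Pavg
    colormap: str = "RdYlGn"  # low P -> red (severe), high P -> green
    smoothing: str = "rbf"  # 'rbf' (Gaussian-weighted) or 'nearest'
    rbf_sigma: float = 0.28  # in normalized ellipse units
    background: tuple[int, int, int] = (255, 255, 255)


def render_heatmap(
    scalp_map: ScalpSeverityMap, options: HeatmapOptions | None = None
) -> np.ndarray:
    """Render the severity heatmap as an 8-bit RGB raster.

    Inside the ellipse each pixel's value is interpolated from the 12 region
    P values ('rbf': normalized Gaussian-weighted average of all centers;
    'nearest': the nearest center's P) and mapped through the colormap.  The
    right margin shows a color bar and the printed Pavg.
    """
    options = options or HeatmapOptions()
    w, h = options.size
    mw = options.margin
    ew, eh = w - mw, h  # ellipse canvas
    a, b = 0.46 * ew, 0.46 * eh  # semi-axes, small outer border
    cx, cy = ew / 2.0, eh / 2.0

    names = scalp_map.layout.names
    centers = np.array([scalp_map.layout.regions[n] for n in names])
    values = np.array([scalp_map.results[n].P for n in names])

    yy, xx = np.mgrid[0:h, 0:ew]
    u = (xx - cx) / a
    v = (yy - cy) / b
    inside = u * u + v * v <= 1.0

    uv = np.stack([u[inside], v[inside]], axis=1)
    if options.smoothing == "rbf":
        d2 = ((uv[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        wts = np.exp(-d2 / (2.0 * options.rbf_sigma**2))
        wts /= wts.sum(axis=1, keepdims=True)
        field_vals = wts @ values
    elif options.smoothing == "nearest":
        d2 = ((uv[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        field_vals = values[np.argmin(d2, axis=1)]
    else:
        raise ValueError(f"unknown smoothing {options.smoothing!r}")

    cmap = colormaps[options.colormap]
    canvas = np.empty((h, w, 3), dtype=np.uint8)
    canvas[:] = np.asarray(options.background, dtype=np.uint8)
    rgba = (cmap(np.clip(field_vals, 0.0, 1.0)) * 255.0).round().astype(np.uint8)
    region = canvas[:, :ew]
    region[inside] = rgba[:, :3]

    # color bar in the margin (P=1 at top)
    bar_x0, bar_w = ew + 18, 22
    bar_y0, bar_y1 = int(0.12 * h), int(0.82 * h)
    ramp = np.linspace(1.0, 0.0, bar_y1 - bar_y0)
    bar_rgb = (cmap(ramp) * 255.0).round().astype(np.uint8)[:, :3]
    canvas[bar_y0:bar_y1, bar_x0 : bar_x0 + bar_w] = bar_rgb[:, None, :]

    img = Image.fromarray(canvas)
    draw = ImageDraw.Draw(img)  # PIL's built-in bitmap font: deterministic
    draw.rectangle([bar_x0 - 1, bar_y0 - 1, bar_x0 + bar_w, bar_y1], outline=(0, 0, 0))
    draw.text((bar_x0 + bar_w + 5, bar_y0 - 5), "1.0", fill=(0, 0, 0))
    draw.text((bar_x0 + bar_w + 5, bar_y1 - 7), "0.0", fill=(0, 0, 0))
    draw.text((ew + 8, int(0.88 * h)), f"Pavg={scalp_map.Pavg:.3f}", fill=(0, 0, 0))
    draw.text((int(cx) - 28, 4), "anterior", fill=(90, 90, 90))
    return np.asarray(img)


def save_heatmap_png(raster: np.ndarray, path) -> None:
    Image.fromarray(raster).save(path)


def write_scalp_json(scalp_map: ScalpSeverityMap, path) -> None:
    """JSON sidecar: per-region P values plus Pavg."""
    doc = {name: p for name, p in scalp_map.P_values.items()}
    doc["Pavg"] = scalp_map.Pavg
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
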