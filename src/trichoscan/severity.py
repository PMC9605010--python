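"""Hair-loss severity scores.

Three quantities summarize follicle-level predictions:

* **PLS** — a per-image weighted label score over follicle bounding-box
  areas.  Two readings are provided: the ``literal`` sum of predicted class
  codes (the area weight cancels algebraically when each follicle's area
  divides itself) and the ``area_weighted`` normalized form
  ``sum(yhat * Area) / sum(Area)`` (default, matching the stated intent of a
  bounding-box-area-weighted sum).

* **Local severity index P** — for one scalp patch (one image) with
  per-class follicle counts ``n_i``, the raw score is
  ``S = sum_i n_i * (alpha_i + beta)`` with class weights
  ``alpha = [32, 22, 12]`` for [healthy, normal, severe] and a per-follicle
  density weight ``beta`` (default 0).  P is S normalized to [0, 1] against
  the fixed saturation score ``S_max = n_max * (alpha_healthy + beta)``
  (``n_max`` = 45, the nominal per-image follicle maximum),
  clamped at 1.  **High P means healthy.**  A fixed scale (rather than
  per-dataset min-max) keeps P comparable across subjects and sessions.

* **Pavg** — the arithmetic mean of P over the (nominally 12) scalp regions;
  the scalp-level severity estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from trichoscan.datamodel import CLASS_NAMES

logger = logging.getLogger(__name__)

#: default class weights, [healthy, normal, severe]
DEFAULT_ALPHA = {"healthy": 32.0, "normal": 22.0, "severe": 12.0}
#: alternative reading with typeset-lost superscripts [3^2, 2^2, 1^2]
SQUARED_ALPHA = {"healthy": 9.0, "normal": 4.0, "severe": 1.0}


@dataclass(frozen=True)
class SeverityParams:
    """Weights and normalization scale for the local severity index.

    alpha must be strictly decreasing from healthy to severe; beta adds a
    flat per-follicle contribution (follicle density); n_max is the follicle
    count at which a patch of all-healthy follicles saturates P at 1.
    """

    alpha: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    beta: float = 0.0
    n_max: int = 45

    def __post_init__(self) -> None:
        missing = set(CLASS_NAMES) - set(self.alpha)
        if missing:
            raise ValueError(f"alpha missing classes: {sorted(missing)}")
        if not (self.alpha["healthy"] > self.alpha["normal"] > self.alpha["severe"] >= 0):
            raise ValueError("alpha must be strictly decreasing healthy > normal > severe >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")

    @property
    def s_max(self) -> float:
        return self.n_max * (self.alpha["healthy"] + self.beta)


@dataclass(frozen=True)
class LocalSeverityResult:
    """Per-patch class counts, raw score S, and normalized index P."""

    k: str | int
    counts: dict
    raw_score: float
    P: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.P <= 1.0):
            raise ValueError(f"P must be in [0, 1], got {self.P}")


@dataclass(frozen=True)
class PlsInput:
    """Aligned per-follicle predicted class codes and bounding-box areas."""

    labels: tuple[int, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.areas):
            raise ValueError("labels and areas must be aligned")
        if len(self.labels) == 0:
            raise ValueError("PLS is undefined for an empty follicle set")
        if any(a <= 0 for a in self.areas):
            raise ValueError("areas must be > 0")


def pls_score(pls_input: PlsInput, variant: str = "area_weighted") -> float:
    """Per-image weighted label score.

    ``literal``: sum of predicted class codes (each follicle's area weight
    Area/Area cancels).  ``area_weighted`` (default): bounding-box-area
    weighted mean label, ``sum(yhat * Area) / sum(Area)``.
    """
    labels = np.asarray(pls_input.labels, dtype=float)
    areas = np.asarray(pls_input.areas, dtype=float)
    if variant == "literal":
        return float(labels.sum())
    if variant == "area_weighted":
        return float((labels * areas).sum() / areas.sum())
    raise ValueError(f"unknown PLS variant {variant!r}")


def local_severity_index(
    counts: dict, params: SeverityParams | None = None, k: str | int = 0
) -> LocalSeverityResult:
    """Local hair-loss severity index P for one patch.

    ``counts`` maps class name -> follicle count (missing classes count 0).
    ``P = min(1, S / S_max)`` with ``S = sum_i n_i (alpha_i + beta)`` and
    ``S_max = n_max * (alpha_healthy + beta)``; P = 0 on an empty patch.
    """
    params = params or SeverityParams()
    unknown = set(counts) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown classes in counts: {sorted(unknown)}")
    full = {name: int(counts.get(name, 0)) for name in CLASS_NAMES}
    if any(v < 0 for v in full.values()):
        raise ValueError(f"counts must be >= 0, got {full}")
    raw = sum(n * (params.alpha[name] + params.beta) for name, n in full.items())
    p = min(1.0, raw / params.s_max)
    return LocalSeverityResult(k=k, counts=full, raw_score=float(raw), P=float(p))


def average_severity(p_values, expected_m: int = 12) -> float:
    """Scalp-level severity Pavg: the arithmetic mean of regional P values.

    Nominally over ``expected_m = 12`` scalp regions; other lengths are
    accepted with a logged warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("average_severity requires at least one P value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    if p.size != expected_m:
        logger.warning("averaging %d P values (nominal layout has %d)", p.size, expected_m)
    return float(p.mean())


def severity_from_labels(
    labels, params: SeverityParams | None = None, k: str | int = 0
) -> LocalSeverityResult:
    """Convenience: local severity index from an iterable of class labels."""
    counts = {name: 0 for name in CLASS_NAMES}
    for label in labels:
        counts[label] += 1
    return local_severity_index(counts, params, k=k)


def write_severity_table(results, path) -> None:
    """Write per-region severity rows (region, counts, S, P) as TSV."""
    with open(path, "w") as fh:
        fh.write("region\tn_severe\tn_normal\tn_healthy\tS\tP\n")
        for res in results:
            fh.write(
                f"{res.k}\t{res.counts['severe']}\t{res.counts['normal']}\t"
                f"{res.counts['healthy']}\t{res.raw_score:.1f}\t{res.P:.6f}\n"
            )
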