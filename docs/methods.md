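# Methods

`trichoscan` implements a trichoscopy analysis pipeline for scalp microscopy
images (nominally 640×480 px at 200× magnification): follicle detection,
rule-based three-class follicle state classification, local and scalp-level
hair-loss severity scoring, and a 12-region severity heatmap. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data generator does and does not establish.

## The follicle state model

A follicle's state is decided by three measurements, all in pixels at the
nominal magnification:

| feature | severe | normal | healthy |
|---|---|---|---|
| follicle radius r | r ≤ 10 | 10 < r < 20 | r ≥ 20 |
| hair count k | k ≤ 1 | k ≤ 1 | k ≥ 2 |
| hair thickness t | t ≤ 3 | 3 < t < 6 | t ≥ 6 |

The defining bands leave two questions open, which the package resolves as
follows:

* **Boundary values.** Band boundaries are closed on the severe-ward side
  (r = 10 is severe, r = 20 is healthy, t = 3 severe, t = 6 healthy) so the
  rule is total. A boundary case flags *more* severity — the clinically
  conservative reading.
* **Conflicting features.** The three criteria are conjunctive only for
  clean-band cases; real measurements can disagree. Default resolution is
  majority voting: each feature votes for the class whose band it falls in,
  a hair count ≤ 1 being consistent with both severe and normal contributes
  half a vote to each, and ties break toward the more severe class. A strict
  all-criteria mode returns `indeterminate` instead. A follicle with no
  visible hair (k = 0) classifies severe: absent hair is at least as severe
  as one thin hair.

Voting makes the classifier monotone — increasing any feature never moves
the output toward severe — which is property-tested.

## Feature measurement

Given an image and a follicle circle (from an annotation or a detection):

* **radius** — the circle's radius (for mask detections, the
  equivalent-area radius).
* **hair count** — hairs are segmented as near-black pixels (gray < 80 on
  the 8-bit scale; the darkened follicle disk stays well above this). The
  count is the number of distinct strand runs crossing the circle boundary,
  found by sampling the boundary at 1440 angles and counting contiguous
  positive runs (circularly joined).
* **hair thickness** — the medial-axis width of the strands, measured in a
  radial annulus 0.55 r–1.00 r from the center. The annulus stays inside
  the follicle disk (where the strand/background contrast cutoff is
  symmetric), away from the near-center region where multiple hairs of one
  follicle merge, and short of the rounded strand tips. The default
  estimator is **area / centerline length**: the strand pixel area inside
  the annulus divided by (number of strands crossing the annulus × its
  radial span). Because strands run radially, the radial span is the
  centerline length per strand, and pixel area integrates the anti-aliased
  coverage, giving sub-pixel accuracy. The more conventional
  skeleton-distance-transform estimators (median/mean/max of 2·EDT−1 along
  the skeleton) are available via `FeatureConfig(thickness_stat=...)`, but
  on a binary mask they quantize to roughly integer steps — a 4–5 px stroke
  reads 3.0 — which is why they are not the default.

## Severity scores

* **Local severity index P** for one image/patch with per-class counts
  n_i: raw score S = Σ_i n_i (α_i + β) with α = [32, 22, 12] for
  [healthy, normal, severe] and β a flat per-follicle density weight
  (default 0; it is part of the model but has no established value, so it
  is exposed as a parameter). P = min(1, S / S_max) with
  S_max = n_max (α_healthy + β) and n_max = 45, the per-image annotation
  maximum of the emulated regime. **High P means healthy** (a fully
  healthy, fully populated patch scores 1). The normalization is a fixed
  scale rather than per-dataset min-max so that P is an absolute index,
  comparable across subjects and sessions; both the scale and an
  alternative α preset [9, 4, 1] (the squares [3², 2², 1²]) are
  configurable. P is monotone non-decreasing in every class count, and
  replacing a severe follicle by a healthy one never decreases it.
* **Pavg** — the arithmetic mean of P over the 12 scalp regions; other
  region counts are accepted with a warning.
* **PLS** — a per-image weighted label score over follicle bounding-box
  areas (boxes are the tight squares around the circles: width = height =
  2r, area = 4r²). Two readings are implemented because the defining formula
  is ambiguous: `literal` (Σ ŷ, each follicle's area ratio cancelling) and
  `area_weighted` (Σ ŷ·Area / Σ Area, the default, matching the stated
  intent of an area-weighted sum). PLS and P are independent outputs; the
  package does not feed one into the other.

## Detection

The deep instance-segmentation stage of a production pipeline (Mask R-CNN
with ResNet-50/101 backbones, or any comparable instance segmenter) is
deliberately **not** reimplemented: training is GPU-scale, suitable labeled
scalp images are not publicly available, and everything downstream is
detector-agnostic. Instead, detection is a contract — detections JSON with
`{image_id, cx, cy, r, score, label?}` — that any external model can fill.

The bundled **reference detector** is classical and deterministic:
grayscale → background flattening (subtraction of a σ = 40 px Gaussian
illumination estimate) → dark-region threshold (flattened value < −30) →
separation of disk pixels from near-black hair pixels (gray < 80) → removal
of the 1-px anti-alias fringe (opening, radius 1) and specks (< 8 px) →
morphological regrouping of disk sectors cut apart by overlying hairs
(closing, radius 6: bridges intra-disk gaps up to the 10 px maximum hair
width, but not the ≥ 16 px gap the simulator guarantees between disks) →
connected components → circle fit. The fitted center is the component
centroid; the radius is the 98th percentile of pixel-to-centroid distance
+ 0.5 px, robust to hair-covered holes in the disk. The confidence score is
the fraction of the fitted circle covered by dark pixels; components with
core area < 30 px² or coverage < 0.55 are rejected.

The per-instance mask loss used by mask-head training is provided
standalone: average binary cross-entropy over an m×m grid, predictions
clipped to [ε, 1−ε] with ε = 10⁻⁷ (the loss is undefined at exactly 0/1).

## Evaluation

Circle-circle IoU is computed in closed form (lens area), with a
raster-counting variant kept as an independent cross-check (they agree
within 0.01 for r ≥ 5 px). Matching is greedy in descending score order;
each detection claims the highest-IoU unmatched truth at IoU ≥ τ. AP uses
all-point interpolation (the precision envelope), and the headline mAP
averages classes over the τ sweep {0.50, 0.55, …, 0.95}, with mAP(50)/
mAP(75) at the single thresholds — the convention implied by those column
names. Classification metrics are one-vs-rest precision/recall/F1 and
accuracy from a 3×3 confusion matrix; the support-weighted
misclassification rate Σ_c support_c·error_c / Σ_c support_c equals
1 − accuracy when both derive from the same matrix (property-tested).
When detections are evaluated end to end, accuracy over matched follicles
is reported both as-is and with unmatched ground truths counted as errors.

## The synthetic-data generator

The generator exists so that every downstream stage is testable with exact
ground truth. It emulates the targeted data regime, not real optics:

* 640×480 RGB canvas; skin tone (210, 180, 160) with ±10% low-frequency
  mottle (Gaussian-filtered noise, σ = 60 px, normalized to its peak) and
  σ = 2 gray-level pixel noise;
* 10–45 follicles per image, class mixture proportional to
  severe : normal : healthy = 3836 : 11262 : 8914;
* a follicle is a softly darkened disk (36% darkening, 2 px linear edge)
  with near-black hairs — anti-aliased quadratic arcs of the prescribed
  thickness, length 1.15–1.5 r, gentle curvature (perpendicular control
  offset ≤ 6% of length), ≥ 75° apart in angle at multi-hair follicles.

**Strict bands.** Sampled (r, k, t) triples fall strictly inside one
class's band so the generating label is the unique rule-consistent label.
Open band boundaries carry a rasterization guard — 0.5 px on radius and
0.75 px on thickness (half-pixel grid quantization plus the anti-alias
threshold offset) — because sub-half-pixel differences at a band edge are
not renderable; e.g. normal thickness is drawn from [3.75, 5.25] inside
the defining (3, 6). The severe thickness band starts at 1.5 px, the
thinnest stroke that rasterizes as a connected strand.

**Placement.** Follicles are placed largest-first by rejection sampling
under a non-overlap policy: pairwise center distance ≥
max(reach_i + r_j, reach_j + r_i, r_i + r_j + 12) + 4 px, where
reach = 1.5 r + 8 bounds hair extent. This guarantees (a) no hair strand
enters another follicle's disk or measurement annulus, so the planted hair
counts and thicknesses are exact ground truth, and (b) a ≥ 16 px gap
between disks, which the detector's regrouping radius respects. A flat
"2.5 × maximum radius" separation was rejected: it either (applied
globally, 80 px) makes the 45-follicle top of the regime unplaceable on a
640×480 canvas, or (applied per pair) lets long hairs of a large follicle
cross a small neighbour. When an image's draw cannot be placed within the
attempt budget (3000 per follicle), the whole image is redrawn from the
same stream (up to 10 times), preserving determinism; the manifest records
the final counts. Overlapping/occluded follicles — a known failure mode of
real trichoscopy — are only produced when `non_overlapping=False`.

**What passing tests do and do not show.** The simulator has uniform
illumination, black hairs on light skin, circular follicles and separated
strands. Success on it demonstrates that the measurement, classification,
scoring and evaluation machinery is correct, and that the classical
detector is sound on well-contrasted images. It does not demonstrate
performance on real scalps (occlusion by hair layers, non-black hair,
oiliness, red spots, off-nominal focus), which is precisely the regime the
pluggable deep-detector contract exists for.

## Other numerical and design choices

* Coordinates are 0-based continuous pixels, x right / y down (the VIA
  convention). Circles crossing the image border are kept unclipped but
  flagged; areas always use the unclipped circle.
* VIA JSON: circle regions only; the class code lives in the region
  attribute `"class"` and is accepted as string or integer, always written
  as a string; writes use sorted keys so write→read→write is
  byte-identical.
* `split_dataset` rounds |train| = ⌊fraction·N + 0.5⌋ (half-up, not
  banker's) and shuffles image ids with a seeded generator.
* Resize uses bilinear interpolation; under anisotropic resize radii scale
  by √(sx·sy) (a circle cannot stay a circle; this preserves the area
  ratio) and the event is logged. Blur uses reflective borders. Slant/
  perspective correction is out of scope — no procedure is defined for it —
  only flips are provided.
* Heatmap: region centers at u ∈ {−0.45, 0, 0.45} × v ∈ {−0.6, −0.2, 0.2,
  0.6} on the unit ellipse (the 3×4 scheme fixes only the topology, not
  coordinates); smoothing is normalized Gaussian-weighted interpolation
  between centers (σ = 0.28 in ellipse units), with a nearest-region block
  mode; colormap RdYlGn (red = severe, green = healthy), configurable.
  Rendering is a pure function of the map and byte-deterministic (PIL's
  built-in bitmap font).

## Problem sizes

The bundled checks run at desk scale on one CPU: the parameter-recovery and
detector suite uses 100 synthetic images (~2600 follicles, ~45 s
total); the simulated-subject comparison uses three subjects × 12 regions;
oracle cross-checks use 1000 random circle pairs and exhaustive AP
enumeration up to six detections. Unit and property tests use smaller
canvases (6 images shared session-wide).

## Known limitations

* The rule thresholds are in pixels at a fixed magnification; no
  pixel↔mm scale is defined, so images must be at the nominal scale (or be
  resized to it) for the bands to be meaningful.
* The reference detector assumes dark follicles/hairs on lighter skin and
  clear separation; it is a desk-scale stand-in by design, not a
  replacement for a learned instance segmenter on real images.
* P's normalization saturates at n_max follicles; patches denser than
  n_max all score 1 regardless of composition beyond that point.
* The strict "all-criteria" classification mode leaves conflicting
  measurements `indeterminate`; downstream severity scoring requires the
  majority-vote mode (or external resolution).
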