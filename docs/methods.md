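# Methods

## Coordinate convention and calibration

Frames are 2-D 8-bit intensity grids with row index increasing with depth
(row 0 nearest the probe) and column index increasing laterally. Pixel pitch
is anisotropic; the default calibration is 0.0023 mm/px axial and
0.0093 mm/px lateral, the self-consistent assignment for a native
3466 × 1386 frame (≈ 8 mm depth, 12.8898 mm width). Calibration is resolved
per image in priority order: manifest-supplied pitches, then ruler
estimation, then the defaults.

Every millimetre-to-pixel conversion uses round-half-up,
`floor(mm/pitch + 0.5)`, so band depths are deterministic and testable:
0.2 mm at 0.0023 mm/px is exactly 87 rows.

Ruler estimation collapses the ruler strip to a 1-D profile along the
requested axis, takes peaks above mean + 2·std with ≥ 3 px separation, and
divides the tick spacing (mm) by the median inter-peak distance. Fewer than
three detected ticks is an error (the manifest pitch should be used); the
parameters are configurable because ruler overlays differ between scanner
firmware versions. Ruler pixels are excluded from the segmentation graph and
from every ROI — the ruler is a graphic, not tissue.

## Entry-echo segmentation

The entry echo layer is segmented by seeded fuzzy connectedness:

* **Seeds.** Per tissue column, the brightest pixel within the top
  `seed_depth_limit_mm` (default 1.5 mm). Seeds whose row deviates from the
  median seed row by more than `seed_row_tolerance_mm` (default 0.2 mm) are
  discarded: the entry echo is a contiguous shallow band, so an outlying
  per-column maximum is a deep bright artifact rather than the layer. Set
  the tolerance to 0 to disable.
* **Affinity.** κ(a,b) = exp(−(I(a)−I(b))²/(2σ²)) between 4-adjacent
  pixels, σ = 25 intensity units by default.
* **Connectedness.** A pixel's connectedness to the seed set is the maximum
  over paths of the minimum affinity along the path. It is computed exactly
  by a best-first (Dijkstra-like) propagation: pixels are settled in
  decreasing connectedness order, so each value is final when popped. The
  mask is the θ-superlevel set (θ = 0.5). Because max–min path strength is
  threshold-monotone, raising θ can only shrink the mask.
* **Pre-filtering.** An optional square median filter (`median_size`) can
  despeckle the image before affinity computation; it is **off by default**.
  A median (or any) smoothing window replaces the sharp step at the layer
  boundary with a ramp of intermediate values; once the per-row increments
  of that ramp drop below the affinity threshold
  σ·√(2·ln(1/θ)) ≈ 29 intensity units, connectedness leaks through the
  boundary and floods the dermis. On speckle whose spatial correlation is
  comparable to the filter size the filtered field is not meaningfully
  smoother, so the ramp is all cost and no benefit. The option remains for
  inputs with heavy uncorrelated noise.

Post-processing (applied to internal and external masks alike): clear
`border_px` = 20 columns at each lateral edge first (acquisition artifacts
concentrate there; this removes 2 · 20 · 0.0093 = 0.372 mm of a native
frame), then remove 8-connected components smaller than `min_object_px`
(default 200 px — deliberately below one column-mm of layer so a genuine
fragment survives), then keep only the largest component, since exactly one
entry echo exists per frame. The operation is idempotent. Crop-first
ordering was chosen so that border artifacts cannot rescue a small component
above the size threshold.

Boundaries are per-column extremes of the cleaned mask: top = shallowest
foreground row, bottom = deepest. Interior holes are intentionally ignored
(the layer is measured as the span between its outer surfaces).

## ROI geometry

With d(x) = round-half-up(x mm / axial pitch) and per-column layer bottom
row b:

* entry echo: the mask itself;
* outer entry echo: rows [top, top + d(0.1) − 1] clipped to the mask —
  clipping keeps the region inside segmented tissue when the layer is
  locally thinner than 0.1 mm;
* upper dermis: rows (b, b + d(0.2)];
* lower dermis: rows (b + d(0.2), b + d(0.2) + d(0.4)].

Bands follow the layer contour column by column (skin layers are locally
near-parallel; contour-following reduces to a global offset for a flat
layer). The dermal bands are strictly adjacent and disjoint. A column whose
band would extend past the image bottom is excluded from that band entirely
rather than padded or truncated, so intensity statistics are never diluted
by missing tissue; excluded columns are reported per ROI.

## Parameters

* **Thickness** — mean over valid columns of (bottom − top + 1) · axial
  pitch. The mean is the default aggregator; a median option exists for
  frames with residual segmentation outliers.
* **Echogenicity** — arithmetic mean of raw 8-bit intensities over the ROI.
  No normalisation is applied: frames of one study share acquisition
  settings, so native levels compare directly.
* **Band fractions** — nLEP/nMEP/nHEP = 100 · (ROI pixels with intensity in
  [0,30] / [50,150] / [200,255], bounds inclusive) / (ROI pixel count).
  Normalising by the region size makes regions of different thickness
  comparable. The three default bands leave 31–49 and 151–199 uncovered, so
  their sum is ≤ 100 %; the five-band partition {[0,30], [31,49], [50,150],
  [151,199], [200,255]} sums to exactly 100 %.
* **nLEP ratio** — upper-dermis nLEP over lower-dermis nLEP; reported as
  missing (NaN), not an error, when the denominator is zero.
* **Roughness** — A/B where A is the physical polyline length through the
  per-column top-boundary points (Σ √(lateral² + (Δrow·axial)²) over
  adjacent valid columns) and B is the lateral width traversed. Gaps in the
  valid columns split the polyline; segments are summed. The top boundary is
  used because it is the skin surface. Each step is normalised by the
  lateral pitch before averaging so a flat boundary yields exactly 1.0 in
  floating point. Rasterisation quantises the boundary to integer rows,
  which inflates the ratio slightly (axial steps of ±1 row appear where the
  continuous boundary crosses row centres); at the default phantom waviness
  this bias is under 1 %.
* **GLCM texture** — intensities are quantised to `levels` = 128 bins by
  floor(I·levels/256); ordered pairs (p, p+offset) are counted only when
  both endpoints lie in the ROI; the transpose is added (symmetric — the
  direction of traversal carries no information here) and the matrix is
  normalised to sum 1. Offsets are (row, column) displacements on the native
  anisotropic grid — (0,7) lateral, (7,7) oblique, (5,7) the intermediate
  default geometry — reported separately, never pooled, since anisotropy
  makes directions non-equivalent. Features: contrast Σ(i−j)²Pij,
  correlation Σ(i−μi)(j−μj)Pij/(σiσj) (NaN for a constant region), energy
  ΣPij², homogeneity ΣPij/(1+|i−j|).
* **Entropy** — Shannon entropy (bits) of the ROI's 128-bin quantised
  histogram, with 0·log 0 ≡ 0. This is region entropy, deliberately distinct
  from the GLCM entropy (available via a flag): it measures intensity
  disorder independently of the co-occurrence geometry.

`measure_all` composes all of the above into one record per frame; regions
that are empty (e.g. a fully truncated lower dermis) or degenerate (no pixel
pairs at an offset, zero marginal variance) yield NaN for their parameters,
and the record is deterministic given its inputs.

## Phantom model

A phantom is assembled from continuous layer boundaries and a correlated
speckle field:

* **Geometry.** The skin surface is a mean depth plus a sum of ≤ 3 sinusoids
  (amplitude and wavelength in mm, phases drawn from the seed). The
  entry-echo bottom contour is the top contour shifted by the layer
  thickness, so the true thickness is exact. Below it lie a dark
  upper-dermis band (SLEB-like, default 0.2 mm) and a brighter lower dermis;
  above it, a dim coupling-gel zone. A pixel belongs to a layer when its
  row-centre depth lies within the layer's continuous bounds. A ruler strip
  of known tick spacing occupies the rightmost columns.
* **Speckle.** A unit-variance Gaussian field with Gaussian spatial
  correlation (default 2 px — the resolution-cell grain, scaled to the
  phantom geometry) is mapped through the normal CDF to a uniform field and
  then through the per-layer target distribution's quantile function. The
  marginal distribution of every pixel is therefore *exact*, while spatial
  correlation mimics speckle texture. Intensities are rounded and clipped to
  [0, 255].
* **Intensity model.** The default marginal is gamma with shape 12
  (CV ≈ 0.29), matching the moderate contrast of *display* B-mode pixels:
  scanners log-compress the RF envelope before display, which strongly
  shrinks the envelope's relative spread. A raw Rayleigh marginal — the
  classical fully-developed-speckle envelope model, CV 0.52 — is available
  (`speckle_model="rayleigh"`) for studies of uncompressed amplitude
  statistics. Rayleigh was not kept as the default because its layer overlap
  is unresolvable for any intensity-difference-based segmentation: with a
  mean-200 layer, 18 % of its pixels fall below 100, so the band/dermis
  boundary contains long stretches that genuinely look like dermis, and
  max–min connectedness either floods through them or fragments the layer
  (verified by exhaustive threshold scans). Layer means default to 200
  (entry echo), 40 (upper dermis), 90 (lower dermis), 10 (gel).
* **Analytic truth.** Thickness and the roughness ratio come from the
  continuous boundaries (arc length by fine trapezoidal quadrature); layer
  means and band fractions from the marginal CDF evaluated at half-integer
  edges, so 8-bit rounding is accounted for, with the clipped upper-tail
  mass assigned to value 255 (hence to the high-echogenicity band). The
  continuous-CDF helper `rayleigh_band_probability` gives the textbook
  closed form (e.g. P(X ≤ 30 | σ = 30) = 1 − e^(−1/2) = 39.35 %); the truth
  record applies the ±0.5 quantisation offsets on top of it.

**Problem sizes.** The default phantom is 400 × 600 px at the native pitches
(≈ 0.9 × 5.6 mm) with 0.2 mm ruler ticks — a cropped field of view rather
than a resampled frame, so per-pixel statistics are unchanged; a
`full_scale` constructor reproduces the 3466 × 1386 geometry with 1 mm
ticks. Recovery tests run 20 seeds of the default geometry.

**What the phantom does not model.** Wave propagation (no attenuation, TGC,
shadowing or refraction), anatomical texture anisotropy (collagen bundles),
layer-boundary transition zones, and scanner annotations other than the
ruler. Passing recovery tests therefore demonstrates the correctness of the
measurement chain on images with realistic first-order statistics, not
segmentation robustness to every clinical artifact — external masks from a
trained segmenter remain the recommended route for difficult clinical data.

## Power analysis

For the between-group main effect of a k-group repeated-measures design with
m measurements and compound-symmetric correlation ρ: f² = η²/(1−η²),
λ = f²·N·m/(1+(m−1)ρ), power = P(F′(k−1, N−k, λ) > F_crit(α)). Averaging m
correlated measures inflates the effective sample size by m/(1+(m−1)ρ); the
F test on subject means is exactly the between-factor test, which is also
how the independent Monte-Carlo cross-check simulates it (unit total
variance split as ρ between subjects and 1−ρ within, group means ±√f²). The
required sample size is the smallest multiple of the group count reaching
the target power.

## Numerical conventions

* mm→px: round-half-up, shared across calibration and ROI code.
* Components: 8-connectivity; affinity graph: 4-adjacency.
* Missing values are NaN in records, empty strings in CSV; CSV numbers are
  written at 10 significant digits so a round trip is value-exact at that
  precision.
* Degenerate inputs raise typed errors (`SegmentationError`,
  `MeasurementError`, …) at the operation level; `measure_all` converts
  per-region degeneracies to missing values but propagates structural
  failures.
* Determinism: phantoms are bit-reproducible from (spec, seed); the
  measurement chain contains no randomness.

## Known limitations

* The fuzzy-connectedness stand-in assumes the entry echo is the brightest
  shallow structure; heavy near-field artifacts would require external
  masks.
* Dermis/subcutis anatomical boundaries are not detected; the dermal ROIs
  are fixed-depth bands referenced to the entry echo.
* GLCM features at offset (5,7) and (7,7) mix axial and lateral physical
  scales because the grid is anisotropic; offsets are reported in pixels by
  design.
* The best-first propagation is exact but single-threaded Python; a native
  frame takes a few tens of seconds. Masks from upstream networks bypass it.
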