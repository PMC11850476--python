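# Methods

## Problem and scope

`organoquant` quantifies bright-field time-lapse series of organoid
cultures: one single-channel frame per well per time point (typically every
4 h up to ~100 h), optionally accompanied by precomputed instance masks and
a plate layout mapping wells to treatment conditions.  The package follows
*regions*, not individual organoid identities: no tracking or linking is
performed across frames, and all kinetic readouts are per-frame aggregates.
Fusion of organoids is therefore observable only through its region-level
signature (count drop with retained area), which is exactly how it is
reported.

## Segmentation

Organoids are dark-rimmed objects on a bright background, so the default
polarity selects pixels *below* an intensity threshold.

1. **Illumination flattening.**  The background field is estimated by a
   Gaussian-weighted local plane fit at scale `background_sigma_px`
   (default 25 px), implemented by normalized convolution: nine Gaussian
   filters with zero padding feed per-pixel 3×3 weighted-least-squares
   normal equations.  A plain Gaussian blur is biased wherever the window
   is one-sided (the entire border zone at these scales); the local plane
   fit is exact for constant and linearly shaded fields everywhere.  The
   image is divided by the estimate and rescaled around the global
   background level, preserving object/background contrast ratios.  The
   flattened image is used **only** for segmentation; all intensity
   measurements are taken from the raw frame (see below).
2. **Threshold.**  Otsu's inter-class-variance threshold on the flattened
   frame by default, or a fixed 8-bit value.  Two guards make empty frames
   well-behaved: a constant image returns an all-zero mask directly, and an
   auto threshold is rejected when the two classes' mean intensities differ
   by fewer than 16 levels.  The latter matters because Otsu *always*
   splits something: on a pure-noise frame it bisects the noise
   distribution, and at 8-connectivity a 50%-density speckle percolates
   into one image-sized component that would defeat the area filter.
   Sixteen levels is ~3× the separation Otsu produces on Gaussian noise of
   the default background SD (5) and far below the ~80-level separation of
   real organoid/background modes.
3. **Hole filling** (binary, optional, default on) — organoid interiors
   brighter than the rim would otherwise punch holes in dark-object masks.
4. **Watershed splitting.**  Touching objects are split by a watershed on
   the negated Euclidean distance transform, seeded at local maxima of the
   lightly smoothed distance map (smoothing sigma = min-distance/4 removes
   rasterization plateaus that would double-seed one object) separated by
   at least `watershed_min_distance_px` (default 15 px).  Components that
   receive no seed are seeded at their distance maximum so no region is
   lost.  `watershed_min_distance_px <= 0` disables splitting (plain
   8-connected components).
5. **Debris filter.**  Regions smaller than `min_area_px` (default 200 px)
   are removed.  Disintegrated organoids leave fragments below this floor,
   so debris never enters any count — matching how sub-threshold debris is
   invisible to the quantification.
6. **Relabeling.**  Surviving instances are relabeled 1..n ordered by
   centroid (row-major), making outputs independent of input label
   permutations and deterministic.

Externally produced masks (`load_labels`) pass through the same debris
filter and relabeling so downstream numbers are identical for both routes.
A source label spread over several disjoint components is split into one
instance per component, enforcing the one-instance-one-component contract.

`star_convexity_score` is a shape-QC helper for ingested masks: it casts
`n_rays` equally spaced rays from the region centroid and reports the
fraction along which the region is visible from the centroid (in-region
samples form a single run starting at the ray origin).  Convex regions
score 1.0; annuli and crescents (centroid outside the region) score 0 on
the affected rays and never raise.

## Phenotyping

Measurements per instance come from standard region properties computed on
the mask with the **raw** frame as intensity image:

* `area_px` — pixel count (`area_um2 = area_px * pixel_size_um²` when a
  pixel size is supplied);
* `mean_intensity` — arithmetic mean of raw 8-bit values over the region.
  Flattened intensities are never used here: the viability cutoff is
  defined on acquired image intensity, and flattening rescales intensities
  and would silently move the boundary;
* `eccentricity = sqrt(1 − λ₂/λ₁)` with `λ₁ ≥ λ₂` the second-central-moment
  eigenvalues: 0 for a circle, →1 for elongated regions.  Regions with
  fewer than 5 px or a degenerate moment matrix get 0 by convention (the
  debris filter removes them in practice).  A mathematically collinear
  region would give exactly 1; the value is clamped to just below 1 to keep
  the documented [0, 1) range.

**Health classification**: `unhealthy` iff `mean_intensity < cutoff`
(strict), default cutoff 50 on the 8-bit scale; 50.0 itself is healthy.
16-bit inputs are full-range rescaled to 8 bit at load (65535→255) so the
cutoff's meaning does not depend on camera bit depth.

## Size bins and kinetics

Areas of a condition's organoids are pooled and four percentile thresholds
computed (default ranks 20/40/60/80, linear interpolation between order
statistics).  Bins are half-open, right-closed:

    Tiny: A ≤ q20 | Small: q20 < A ≤ q40 | Medium: q40 < A ≤ q60 |
    Large: q60 < A ≤ q80 | Huge: A > q80

Ties at a threshold fall into the lower bin (deterministic, boundary-
stable).  The pooling scope is configurable (`bin_scope`):
`condition_pooled` (default; all organoids of all time points of the
condition — a given physical size keeps its bin over time, so bin-occupancy
kinetics are interpretable), `baseline_only` (first time point only), or
`per_frame`.  Thresholds are computed once per scope and then frozen.

Per-frame summaries hold count, total and mean area, mean eccentricity,
healthy/unhealthy counts and per-bin counts; empty frames carry explicit
absences (`None`), never zeros, for the means.  Every metric is exported
normalized to its first-time-point value; a missing or zero baseline is an
error naming the well and metric (recorded per metric in the run manifest,
never an infinity) — e.g. a fully healthy well legitimately cannot
normalize its unhealthy count.  Baselines are per well by default;
condition-level baselines (mean of the condition's well baselines) are
available via `baseline_scope`.

**Merge detection** flags consecutive frame pairs where the count decreases
while total area does not decrease by more than `area_tolerance` (default
0.1, relative to the earlier frame).  The tolerance trades off growth
between frames (area rises a few percent per 4 h at typical growth rates)
against the area share of a dying organoid; with default scenes a single
death among ~30 organoids removes only ~3% of total area and would be
indistinguishable from a merge at the region level — the flag is a
*candidate* marker, sound in regimes where individual deaths remove more
than the tolerance.

## Synthetic movies

The generator renders the minimal phenomenology the pipeline must survive;
it is not an optics simulation.  Organoids are ellipses with a dark rim
(outer 15% of the radius, area fraction ≈ 0.28) around an interior zone,
on Gaussian background noise; pixel values are the zone value plus small
per-pixel noise, rounded to uint8.

* **Geometry**: initial semi-major axis uniform in `radius_range_px`
  (default 10–22 px; the smallest alive organoid then has ~300 px ≥ the
  200 px debris floor), axis ratio 0.6–1.0, uniform orientation; placement
  by rejection sampling with enough padding that organoids stay inside the
  image for the whole series.  Without merging, initial spacing includes
  the full growth horizon so instances never touch; with merging they may
  grow into contact.  An unsatisfiable request raises a capacity error
  naming the limiting parameter.
* **Growth**: `area(t) = area₀ · exp(g t)` (semi-axes scale by
  `exp(g t/2)`), default `g = 0.008/h` (~2.2× area over 100 h).
  Exponential growth was chosen over logistic for its single parameter.
* **Death**: per frame, an alive organoid starts dying with probability
  `1 − exp(−h·Δt)`; `h = death_hazard_per_h(dose) + slope · area` (default
  linear map 0.0025/h per dose unit, slope 0).  Hazard uniforms are drawn
  for every organoid every frame regardless of state, so under a shared
  seed death times are *pathwise* monotone in dose — the dose-monotonicity
  check is exact, not statistical.  A dying organoid stops growing and its
  interior darkens at `darkening_rate_per_h` (default 2 intensity/h); once
  the analytic two-zone region mean falls below 50 it stays visibly dark
  for one more frame (so the health classifier must see the unhealthy
  state), then disintegrates into `debris_fragments_on_death` fragments of
  2–4 px radius — rendered in the image, absent from truth masks, and far
  below the detection floor.
* **Merging**: when enabled, two overlapping *alive* instances fuse; the
  larger absorbs the smaller (event logged as absorbed/survivor/frame),
  the union is rendered and labeled under the survivor, and absorbed labels
  never reappear.  Truth-mask pixel conflicts between distinct instances
  are resolved by normalized ellipse distance.

The truth table records per frame and organoid the geometry, interior
intensity, life state (`alive → dying → dead`, never reversed), mask label
and rasterized area, plus an event log (dying onsets, deaths, merges).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: out-of-focus and mixed-plane optics, non-elliptic
and lobulated organoid shapes, PBMCs and other small motile objects,
intensity drift of healthy organoids, organoids shrinking rather than
freezing while dying, partial fusions that later separate, and stage
drift.  Accuracy numbers on synthetic scenes (exact counts, IoU ≈ 1) are
upper bounds that certify the machinery, not expected field performance.

## Scenario choices in tests and the acceptance script

* **Clean recovery** uses the default study conditions (25 frames, 4-h
  cadence, 512×512, 30 organoids), merging and dose off: recovered counts
  must equal truth exactly and per-instance IoU ≥ 0.8.
* **Dose ladder** (0/5/15/40 abstract units) runs with merging off so the
  count kinetics isolate killing; final normalized counts must be
  non-increasing in dose.
* **Size-targeted killing** (hazard slope 1e-5 per px²·h) runs
  growth-arrested, emulating a high-dose antiproliferative regime: with
  baseline-frozen bins and growth on, surviving small organoids migrate
  out of the Tiny bin and confound the direction of the share shift.  The
  Huge-bin normalized count must fall below 1 and the Tiny-bin share rise.
* **Merge exactness** is checked through the mask-ingestion route
  (summaries computed from truth masks): the simulator fuses instances at
  first pixel overlap, where a watershed may legitimately still split the
  barely-touching pair for one frame, so the kinetics-level flagging
  contract is exercised on exact counts.
* **Death-only no-flag** uses six near-equal organoids with growth 0, the
  regime where each disintegration removes more than the 10% area
  tolerance (see merge detection above).
* Problem sizes throughout (224–512 px frames, 5–40 organoids, 5–25
  frames, 3 replicates for direction measures) were chosen as the smallest
  scenes that exercise each contract with non-trivial populations.

## Numerical and interface choices

* All frames are 8-bit after load; 16-bit full-range mapping is the
  default (a percentile mapping would couple the health cutoff to scene
  content).
* Percentiles use linear interpolation between order statistics — the
  conventional default, and the one the brute-force oracle in the tests
  implements independently.
* Relabeling order (centroid row-major), record order (by label), row
  order of every exported table (condition, well, time, metric) and CSV
  float formatting (shortest round-trip repr) are all fixed, so identical
  inputs + config + seed give byte-identical outputs.
* Well isolation: any failure while processing a well is logged, recorded
  in the run manifest, and does not abort other wells; per-metric
  normalization failures are recorded separately from well failures.

## Known limitations

* The classical backend assumes dark objects on a bright background with
  roughly unimodal background illumination; it is a desk-scale stand-in
  sharing the output contract of a learned star-convex segmenter, not a
  replacement for one on difficult real data (use `load_labels` to ingest
  such masks).
* Merge flags are region-level candidates (see above), not verified fusion
  events.
* `bin_scope=condition_pooled` makes bin boundaries depend on the whole
  series; adding frames changes thresholds (use `baseline_only` for
  streaming analyses).
* Eccentricity from second moments is meaningful only well above the
  5-pixel degeneracy floor; it saturates slowly for lobulated shapes that
  are not ellipse-like.
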