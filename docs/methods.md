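# Methods

This note documents the measurement model implemented by `lnptrace`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a user should know about.

## The experiment being modelled

Cells expressing a fluorescent membrane-damage sensor (galectin-9 or CHMP2A)
and optionally a compartment marker (e.g. Rab5) are incubated with
fluorescently labeled RNA-LNPs and imaged by high-speed widefield
microscopy: multi-channel z-stacks (~20 planes, 300–500 nm step) for 100–200
time-points at 2.2–3.0 s intervals, ~100 nm pixels. Vesicles carrying RNA
are tracked; when the damage sensor is recruited de novo to a tracked
vesicle, that frame defines the event onset t0. The quantities of interest
are: what fraction of damaged vesicles carried detectable RNA ("hit rate"),
how often and how much RNA leaves the vesicle at damage ("fast release",
release magnitude), which endosomal compartment was damaged (marker
positivity), and — at super-resolution, in fixed cells — where on the
endosome the damage sits relative to the LNP (sub-endosomal geometry).

## Trace quantification

Per tracked vesicle and frame, in order:

1. **Mask fit.** A disc mask of 6 px diameter (≈620 nm at 103 nm pixels) and
   one z-plane depth is moved over an integer grid (±3 px lateral, ±1 plane
   axial by default) around the seed to maximize total in-mask RNA
   intensity. Ties resolve to the smallest displacement from the seed, then
   lexicographically in (dz, dy, dx). A pixel belongs to the disc when its
   center lies within the mask radius.
2. **Local background.** Median pixel intensity of an annulus centered
   8 px outside the mask radius. The annulus is realized as a 2-px-wide ring
   (configurable) at radius `mask_radius + 8`: the narrowest literal reading
   that still yields a robust median sample. Ring pixels falling outside the
   image are excluded. The per-frame background series is smoothed by an
   11-frame centered rolling mean (truncated at the series edges) before
   subtraction.
3. **Bleach correction.** Photobleaching is fitted as a single exponential
   `exp(-k t)` on pooled reference traces of event-free vesicles, each
   normalized to its first measurement (at least 3 traces spanning ≥2 min).
   Pooling (rather than averaging per-trace fits) weighs long traces more
   and is numerically stabler at small n. A negative fitted rate is clamped
   to zero — no "unbleaching". Correction multiplies by `exp(+k t)` in
   absolute acquisition time.
4. **Alignment and normalization.** Times are aligned so t = 0 is the event
   onset (an input: onsets come from inspection or upstream detection, and
   are deliberately not inferred here). The RNA trace is normalized to its
   mean over the window ~3–60 s before onset; damage-marker traces to their
   maximum; compartment-marker traces are left in corrected units, as their
   normalization is per cell (below). Windows specified in seconds convert
   to frames by rounding outward (floor on the near edge — but at least one
   frame from t0 — and ceiling on the far edge), so different frame
   intervals never empty a window.

## Event classification

* **Hit** — the pre-onset (2.2–30 s) background-corrected RNA mean exceeds
  `k` times the noise scale, with `k = 3` by default. The noise scale is the
  mean SD of the background-ring pixels at the vesicle position. This is an
  auditable surrogate for the visual "detectable payload" judgment;
  ring-pixel SD overestimates the noise of a 29-pixel mask mean, making the
  default conservative. Raising `k` can only lower the hit rate (tested).
* **Fast release** — mean normalized RNA over 2.2–30 s after onset below the
  pre-onset mean minus one pre-onset sample SD (ddof = 1). The rule operates
  on normalized traces and is invariant to rescaling the raw data.
* **Release magnitude** — `1 −` the normalized level in the frame nearest
  t0 + 10 s, summarized by the median with a distribution-free
  order-statistic 95 % CI (ranks from the Binomial(n, ½) tails;
  conservative, no distributional assumptions; omitted below 5 events).
* **Marker positivity** — the marker intensity of the five measurements
  (11 s) centered on onset is divided by the per-cell 90th-percentile
  reference `p90(t)`, linearly interpolated between acquisition start and
  end; positive iff the mean strictly exceeds 0.5. Cells whose reference is
  non-positive anywhere in the acquisition are excluded.
* **Load subgroups** — terciles of pre-onset corrected RNA intensity, ties
  to the lower group; a galectin response subgroup helper uses a median
  split on the peak normalized response.

Marker scoring presumes the vesicle is tracked on its RNA signal, so in
cohort analyses it is meaningful for RNA-positive (hit) vesicles; for
simulated RNA-free vesicles the mask fit has nothing to lock onto and the
marker readout degrades accordingly.

## Registration

Reference fields of 0.1 µm beads imaged in all channels calibrate alignment:

* **Detection** — local maxima above a robust threshold; sub-pixel
  intensity-weighted centroids in a window (default radius 10 px) after
  background subtraction; beads whose window clips the border are excluded.
* **Integer shift** — the translation (dx, dy, dz) maximizing the number of
  bead pairs within a 0.5 px match radius, searched over candidates given by
  rounded pairwise centroid differences. Ties resolve to the smallest shift
  norm, then lexicographically. The radius must stay below 0.5 px so that
  neighboring integer shifts cannot tie with the true one.
* **Chromatic model** — after the integer shift, mutual-nearest-neighbor
  matches within 5 px give residual displacements; residual dx is regressed
  on x and dy on y (least squares). A degenerate position range fixes the
  slope at 0 with the mean residual as intercept. The applied correction is
  rounded to the nearest integer pixel per column/row — 1-px accuracy, no
  interpolation of image data. The axial model is an integer shift only.
* An integer part of a constant chromatic offset can be absorbed by the
  shift stage; the physically meaningful quantity is shift + intercept,
  which is what recovery tests compare.

## Sub-endosomal geometry

Per endosome (from 120-px-scale fixed-cell ROIs with a mask): the center of
mass of the endosome-marker channel inside the mask; up to three local
maxima per channel (8-neighborhood peaks above the in-mask median plus one
SD, plateaus resolved to their centroid, non-maximum suppression at 3 px,
3×3 center-of-mass sub-pixel refinement — required because magnitude
differences below the pixel size are reported); vectors from the center to
each maximum. Damage-marker and LNP maxima are paired by the assignment
minimizing the total angular difference (exhaustive over ≤3×3), an
objective surrogate for manual pairing of nearby maxima; the best one or two
pairs are kept. Angular differences are folded to [0°, 180°]; the magnitude
difference is (marker radius − LNP radius) × pixel size.

**Random null.** With one maximum per channel at independent uniform
angles, the folded difference is uniform on [0°, 180°] with mean 90°. For
endosomes with two maxima per channel, the null places the two maxima of a
channel 180° apart (as for two LNPs on opposite membrane sides) at
independent uniform rotations and pairs each marker maximum to the nearest
LNP maximum, giving matched differences uniform on [0°, 90°] with mean 45°.
The construction is verified by deterministic grid enumeration in the tests;
`angular_null` reproduces both means by Monte-Carlo. An alternative null
with fully independent within-channel maxima is conceivable; the antipodal
construction is the one implemented and stated.

## Spot sizing and distances

FWHM of single LNPs is measured by nonlinear least squares of an elliptical
2D Gaussian with constant offset (moment-based initialization);
`FWHM = 2·sqrt(2·ln 2) · σ` holds exactly for every converged fit by
construction, with σ the mean of the two axes in nm. Non-converged fits are
flagged and excluded from summaries. Distances of foci from the nucleus
centroid are min–max normalized over all foci of a cell across the compared
channels; cells with fewer than two foci or zero spread are excluded.

## Foci analysis

Foci are enhanced by subtracting a median-filtered image (default kernel
9 px — the source protocol does not state a size; exposed in config) and
clamping at zero, then segmented as 8-connected components above a manual
per-channel threshold with an area filter. Counts are divided by the number
of cells in the first frame and baseline-subtracted (mean per-cell count at
acquisition start); values are reported as computed and may be slightly
negative. Colocalization: either both foci sets are resized to 5-px discs at
their centroids and any shared pixel counts, or label-image objects
colocalize when the pixels shared with a single partner object strictly
exceed 25 % of the object's area — an asymmetric relation by construction.
Segmentation of diffuse structures uses a configurable global threshold
(default Otsu is available via scikit-image) rather than the
maximum-correlation thresholding of the original CellProfiler pipelines,
which is not specified in text form; outputs should be interpreted
accordingly.

## Synthetic data: what it emulates, and what it does not

The generator renders isotropic 2D Gaussian spots per z-plane with a 1D
Gaussian axial amplitude profile — the simplest model sufficient for mask,
centroid and FWHM tests. Vesicles follow a reflected Gaussian random walk
(default 0.3 px/frame) and keep a minimum separation at placement, matching
the protocol's exclusion of interacting vesicles. Damage events place a
ramping damage-marker spot at the onset frame and, for fast-releasing
vesicles, drop the RNA amplitude by the configured fraction at onset.
Noise is Poisson shot noise followed by Gaussian read noise (a standard
sCMOS approximation), applied last; with all noise disabled the expected
image is returned in floating point, so noiseless fixtures are
quantization-free. Bead fields displace non-reference channels by an integer
shift plus `slope·x + intercept` per axis. Endosome scenes are annular
membranes with per-channel foci at specified or random angles.

Defaults are the study conditions: 103 nm pixels, 2.2 s frame interval,
500 nm z-step, hit fraction 0.70, fast-release fraction 0.26, release
magnitude 0.24, marker-positive fraction 0.62. Camera gain, absolute
intensities and noise levels are free parameters (background 100 counts,
read noise 2, spot amplitude 400) chosen to give a realistic single-spot
SNR ~10–20; they are not calibrated to any instrument. Desk-scale geometry
(5 z-planes, 64 frames, 160–256 px fields) keeps full-cohort simulations in
the seconds-to-minutes range; all axes scale via the config.

Not emulated: Airy rings or depth-dependent aberrations beyond the linear
chromatic model, vesicle fusion/fission or crossing tracks, cytosolic
background structure, slow (non-step) release kinetics, and detector
fixed-pattern noise. Passing tests therefore demonstrate correctness of the
measurement chain under the stated model, not robustness to every real-data
pathology (e.g. tracking errors on crossing vesicles are out of scope, as
tracking itself is an input).

## Determinism and conventions

A single top-level seed drives every simulation; sub-generators derive from
it via `numpy.random.SeedSequence`, and identical config + seed yields
bit-identical stacks and truth tables. Arrays are ordered (c, t, z, y, x),
0-based, pixel-center convention; exported tables use (x, y) column order.
The YAML sidecar, not TIFF tags, is the authoritative metadata source.

## Known limitations

* Event onset (t0) detection is an input, not implemented — onsets in real
  data were identified by inspection.
* The hit threshold and the weak/strong damage-response split are auditable
  surrogates for visual judgments; absolute hit rates depend on `k`.
* The chromatic correction is 1-px accurate by design; sub-pixel residuals
  remain after alignment.
* Marker positivity for RNA-free vesicles is unreliable because tracking is
  RNA-based (see above).
* Cohort recovery tests use two-sided 99 % binomial margins around the
  configured fractions; with fixed seeds this is a deterministic check, but
  the margin itself reflects finite-sample scatter, not classifier error,
  which is separately bounded by truth-agreement assertions.
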