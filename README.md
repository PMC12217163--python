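# lnptrace

Quantitative microscopy analysis of **LNP-mediated endosomal escape of RNA**.

Lipid nanoparticles (LNPs) deliver siRNA and mRNA into cells, but the cargo
only becomes active after escaping from endosomes — a rare event that is
studied by high-speed live-cell fluorescence microscopy: labeled RNA is
tracked on single vesicles while a cytosolic damage sensor (galectin-9,
or the ESCRT component CHMP2A) reports membrane damage by being recruited to
the damaged endosome. `lnptrace` implements the full measurement chain for
such experiments, for microscopists and image analysts who want a tested,
scriptable alternative to one-off analysis code:

* **Synthetic data with ground truth** (`lnptrace.simulate`) — renders
  multi-channel, multi-z time-lapse stacks of moving diffraction-limited
  vesicles with damage-onset events, step-wise partial RNA release,
  photobleaching, per-cell marker heterogeneity, Poisson + read noise, bead
  reference fields with programmed shifts and chromatic offsets, and
  fixed-cell endosome scenes. Every rendered object has a truth record, so
  every downstream module is testable without any external data.
* **Channel registration** (`lnptrace.registration`) — bead-based integer
  shift fitting (1 px lateral / 1 z-interval axial) plus a linear lateral
  chromatic-aberration model per axis.
* **Single-vesicle traces** (`lnptrace.traces`) — a 6-px disc mask re-fitted
  to the local RNA maximum, local background as the median of an annulus
  8 px outside the mask with an 11-frame rolling average, exponential
  photobleaching correction fitted on event-free reference vesicles, and
  event-aligned normalization (RNA to its pre-damage mean ~3–60 s before
  onset; damage markers to their maximum).
* **Event classification** (`lnptrace.events`) — *hit* (detectable RNA
  payload before damage), *fast release* (post-onset mean below the
  pre-onset mean minus one SD, both over ~2.2–30 s windows), release
  magnitude at ~10 s with a distribution-free 95 % CI of the median, and
  compartment-marker positivity against 0.5 × the per-cell 90th-percentile
  reference with a linear time drift.
* **Foci analysis** (`lnptrace.foci`) — median-filter background
  subtraction, thresholded 8-connected foci, baseline-subtracted per-cell
  counts, uptake intensity, control normalization, and two object-based
  colocalization rules (5-px resized discs; strict >25 % area overlap).
* **Spot and endosome geometry** (`lnptrace.geometry`) — 2D-Gaussian FWHM
  spot sizing, nucleus-distance statistics normalized to the inner/outermost
  foci per cell, and the sub-endosomal vector analysis: angles and
  magnitudes between damage-marker and LNP vectors from the endosome's
  center of mass, with its Monte-Carlo random-localization null (90° for one
  paired maximum, 45° for two antipodal paired maxima).

## Worked example

Simulate two fields of damaged vesicles under realistic acquisition
conditions (103 nm pixels, 2.2 s frame interval, Poisson + read noise,
photobleaching), quantify and classify every event, and summarize:

```python
import json
from lnptrace import SimulationConfig, run_synthetic_cohort

cfg = SimulationConfig(n_cells=4, n_vesicles_per_cell=12,
                       height=256, width=256)
truth, events, summary = run_synthetic_cohort(cfg, n_fields=2, seed=42)
print(json.dumps(summary, indent=2, default=float))
```

```json
{
  "n_events": 96,
  "hit_rate": 0.6354166666666666,
  "fast_release_fraction": 0.29508196721311475,
  "release_magnitude": {
    "median": 0.2390116521038957,
    "n": 18,
    "ci_low": 0.23141658015229638,
    "ci_high": 0.24964612331285196
  }
}
```

96 damaged vesicles were simulated with a configured hit fraction of 0.70, a
fast-release fraction of 0.26 and a release magnitude of 0.24. The pipeline —
operating purely on the rendered pixels — estimates a hit rate of 0.64 and a
fast-release fraction of 0.30 (both within binomial sampling error of the
configured truth at n = 96), and a median release magnitude of 0.239 whose
95 % CI [0.231, 0.250] covers the configured 0.24.

The same steps are available from the shell:

```bash
lnptrace simulate release --out data/ --seed 1
lnptrace quantify --stack data/stack.tif --tracks data/seeds.csv \
    --t0 events.csv --out traces.csv
lnptrace classify --traces traces.csv --out-events events.csv \
    --out-summary summary.json
```

plus `lnptrace simulate beads|endosomes`, `lnptrace register`,
`lnptrace foci` and `lnptrace geometry`.

## Documentation

See `docs/methods.md` for the measurement model, parameter defaults,
numerical choices, what the synthetic data does and does not emulate, and
known limitations.
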