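"""Damage-event classification and cohort summaries.

Classifies each vesicle damage event on its event-aligned trace:

* **hit** — detectable RNA payload before damage (pre-event corrected mean
  above ``k`` times the local background pixel noise, ``k`` = 3 by default; an
  auditable surrogate for visual detectability);
* **fast release** — mean normalized RNA intensity ~2.2-30 s after
  damage-marker onset below the pre-onset mean minus one pre-onset SD;
* **marker positive** — mean compartment-marker intensity in the 11 s
  (five-measurement) window centered on onset above 0.5 of the per-cell 90th
  percentile reference (strict inequality), with the reference interpolated
  linearly in time between the start and end of the acquisition.

Cohort level: hit rate, fast-release fraction, the median release magnitude
at ~10 s after onset with a distribution-free (order-statistic) 95% CI, and a
tercile subgrouping by RNA load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .traces import TraceSeries, window_to_frames

logger = logging.getLogger("lnptrace")


@dataclass
class MarkerNormalizer:
    """Per-cell time-dependent 90th-percentile marker reference p90(t)."""

    cell_id: int
    p90_start: float
    p90_end: float
    t_start_s: float
    t_end_s: float

    def p90(self, t_s: float | np.ndarray) -> np.ndarray:
        span = self.t_end_s - self.t_start_s
        slope = (self.p90_end - self.p90_start) / span if span else 0.0
        return self.p90_start + slope * (np.asarray(t_s, dtype=float)
                                         - self.t_start_s)

    def is_valid(self) -> bool:
        """p90(t) must stay positive over the whole acquisition."""
        return (self.p90(self.t_start_s) > 0) and (self.p90(self.t_end_s) > 0)


@dataclass
class VesicleEvent:
    """Classification record of one damage event."""

    vesicle_id: int
    cell_id: int = 0
    hit: bool = False
    fast_release: bool = False
    pre_mean: float = np.nan
    pre_sd: float = np.nan
    post_mean: float = np.nan
    release_magnitude: float = np.nan
    pre_load: float = np.nan            # pre-event corrected RNA intensity
    marker_positive: bool | None = None
    marker_normalized_mean: float = np.nan
    galectin_magnitude: float = np.nan

    def __post_init__(self) -> None:
        if self.fast_release and not self.hit:
            raise ValueError("fast_release implies hit")


def _event_window_values(trace: TraceSeries, channel: str, attr: str,
                         lo_f: int, hi_f: int, side: str) -> np.ndarray:
    values = getattr(trace.channels[channel], attr)
    if side == "pre":
        m = (trace.frames >= trace.t0_frame - hi_f) & \
            (trace.frames <= trace.t0_frame - lo_f)
    else:
        m = (trace.frames >= trace.t0_frame + lo_f) & \
            (trace.frames <= trace.t0_frame + hi_f)
    return np.asarray(values)[m]


def classify_fast_release(trace: TraceSeries, *, rna_channel: str = "rna",
                          window_s: tuple[float, float] = (2.2, 30.0)
                          ) -> tuple[bool, float, float, float]:
    """Fast-release rule on the normalized, bleach-corrected RNA trace.

    Returns ``(flag, pre_mean, pre_sd, post_mean)`` where
    ``flag = post_mean < pre_mean - pre_sd`` over the ~2.2-30 s windows
    before and after onset.  The SD is the sample SD (ddof=1).
    """
    lo, hi = window_to_frames(window_s[0], window_s[1], trace.frame_interval_s)
    pre = _event_window_values(trace, rna_channel, "normalized", lo, hi, "pre")
    post = _event_window_values(trace, rna_channel, "normalized", lo, hi, "post")
    if len(pre) < 2 or len(post) < 2:
        raise ValueError(
            f"vesicle {trace.vesicle_id}: fast-release windows need >= 2 frames "
            f"(have {len(pre)} pre, {len(post)} post)"
        )
    pre_mean = float(pre.mean())
    pre_sd = float(pre.std(ddof=1))
    post_mean = float(post.mean())
    return post_mean < pre_mean - pre_sd, pre_mean, pre_sd, post_mean


def classify_hit(trace: TraceSeries, *, rna_channel: str = "rna",
                 detection_k: float = 3.0,
                 window_s: tuple[float, float] = (2.2, 30.0)) -> bool:
    """Detectable-payload rule: pre-event background-corrected RNA mean above
    ``detection_k`` times the background pixel noise SD at the vesicle.

    When the ring-pixel noise is unavailable (traces rebuilt from CSV), the
    noise scale falls back to the SD of first differences of the pre-event
    corrected trace divided by sqrt(2).
    """
    lo, hi = window_to_frames(window_s[0], window_s[1], trace.frame_interval_s)
    pre = _event_window_values(trace, rna_channel, "corrected", lo, hi, "pre")
    noise = _event_window_values(trace, rna_channel, "background_sd", lo, hi, "pre")
    if len(pre) == 0:
        raise ValueError(f"vesicle {trace.vesicle_id}: empty pre-damage window")
    noise_scale = float(np.nanmean(noise)) if np.isfinite(noise).any() else np.nan
    if not np.isfinite(noise_scale):
        if len(pre) > 1:
            noise_scale = float(np.diff(pre).std(ddof=1) / np.sqrt(2.0))
        else:
            noise_scale = 0.0
    return bool(pre.mean() > detection_k * noise_scale)


def pre_event_load(trace: TraceSeries, *, rna_channel: str = "rna",
                   window_s: tuple[float, float] = (2.2, 30.0)) -> float:
    """Pre-event corrected RNA intensity (the vesicle's RNA load)."""
    lo, hi = window_to_frames(window_s[0], window_s[1], trace.frame_interval_s)
    pre = _event_window_values(trace, rna_channel, "corrected", lo, hi, "pre")
    return float(pre.mean()) if len(pre) else np.nan


def release_level_at(trace: TraceSeries, at_time_s: float = 10.0, *,
                     rna_channel: str = "rna") -> float:
    """Normalized RNA level in the frame nearest ``t0 + at_time_s``."""
    idx = int(np.argmin(np.abs(trace.times_s - at_time_s)))
    return float(trace.channels[rna_channel].normalized[idx])


def median_ci(values: np.ndarray, confidence: float = 0.95
              ) -> tuple[float, float]:
    """Distribution-free order-statistic CI of the median.

    The interval ``(x_(l+1), x_(u))`` with binomial tail probabilities at most
    ``(1-confidence)/2`` on each side; conservative at small n.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    alpha = 1.0 - confidence
    # largest j with P(Binom(n, 1/2) <= j) <= alpha/2
    j = int(stats.binom.ppf(alpha / 2, n, 0.5))
    if stats.binom.cdf(j, n, 0.5) > alpha / 2:
        j -= 1
    # CI = (X_(j+1), X_(n-j)) in 1-based ranks: P(B < j+1) <= alpha/2 for
    # B ~ Binom(n, 1/2), symmetric above
    lo_idx, hi_idx = j, n - j - 1   # 0-based
    if j < 0 or lo_idx > hi_idx:    # too few observations: whole range
        lo_idx, hi_idx = 0, n - 1
    return float(x[lo_idx]), float(x[hi_idx])


def release_magnitude_summary(events: list[VesicleEvent], *,
                              min_n_for_ci: int = 5
                              ) -> dict[str, float | None]:
    """Median fractional RNA drop at ~10 s after damage among fast-release
    events, with a 95% order-statistic CI of the median (omitted below
    ``min_n_for_ci`` events)."""
    drops = np.array([e.release_magnitude for e in events
                      if e.fast_release and np.isfinite(e.release_magnitude)])
    if len(drops) == 0:
        raise ValueError("no fast-release events with a release magnitude")
    out: dict[str, float | None] = {
        "median": float(np.median(drops)),
        "n": int(len(drops)),
        "ci_low": None,
        "ci_high": None,
    }
    if len(drops) >= min_n_for_ci:
        lo, hi = median_ci(drops)
        out["ci_low"], out["ci_high"] = lo, hi
    else:
        warnings.warn(
            f"only {len(drops)} fast-release events; CI of the median omitted")
    return out


def classify_marker_positive(trace: TraceSeries, normalizer: MarkerNormalizer,
                             *, marker_channel: str = "marker",
                             threshold: float = 0.5,
                             n_measurements: int = 5
                             ) -> tuple[bool, float]:
    """Compartment-marker positivity around damage onset.

    The bleach-corrected marker intensity of the five measurements centered
    on t0 is divided by the per-cell p90(t) reference; the vesicle is marker
    positive iff the mean normalized value strictly exceeds *threshold*.
    """
    if not normalizer.is_valid():
        raise ValueError(
            f"cell {normalizer.cell_id}: p90 reference non-positive during "
            "acquisition; event excluded"
        )
    half = n_measurements // 2
    m = np.abs(trace.frames - trace.t0_frame) <= half
    if m.sum() < n_measurements:
        raise ValueError(
            f"vesicle {trace.vesicle_id}: need {n_measurements} measurements "
            f"centered on t0 (have {int(m.sum())})"
        )
    values = np.asarray(trace.channels[marker_channel].bleach_corrected)[m]
    t_abs = trace.frames[m] * trace.frame_interval_s
    normalized = values / normalizer.p90(t_abs)
    mean = float(normalized.mean())
    return mean > threshold, mean


def subgroup_by_load(events: list[VesicleEvent], n_groups: int = 3
                     ) -> np.ndarray:
    """Tercile (n-tile) split on pre-damage RNA load; ties go to the lower
    group.  Returns integer labels 0 (low) .. n_groups-1 (high)."""
    loads = np.array([e.pre_load for e in events], dtype=float)
    if len(loads) < n_groups:
        raise ValueError(f"need at least {n_groups} events")
    edges = np.quantile(loads, np.linspace(0, 1, n_groups + 1)[1:-1])
    labels = np.zeros(len(loads), dtype=int)
    for edge in edges:
        labels += loads > edge      # ties at an edge stay in the lower group
    if np.ptp(loads) == 0:
        warnings.warn("all loads equal; every event assigned to the low group")
        labels[:] = 0
    return labels


def subgroup_by_galectin_response(events: list[VesicleEvent]) -> np.ndarray:
    """Weak/strong damage-response split: median split on the peak normalized
    galectin recruitment (0 = weak, 1 = strong; ties go to weak)."""
    mags = np.array([e.galectin_magnitude for e in events], dtype=float)
    if not np.isfinite(mags).any():
        raise ValueError("no events with a galectin magnitude")
    return (mags > np.nanmedian(mags)).astype(int)


def classify_event(trace: TraceSeries, *,
                   normalizer: MarkerNormalizer | None = None,
                   rna_channel: str = "rna",
                   damage_channel: str = "galectin",
                   marker_channel: str = "marker",
                   detection_k: float = 3.0,
                   release_at_s: float = 10.0) -> VesicleEvent:
    """Run all per-event classifications on one trace."""
    hit = classify_hit(trace, rna_channel=rna_channel, detection_k=detection_k)
    fast, pre_mean, pre_sd, post_mean = classify_fast_release(
        trace, rna_channel=rna_channel)
    fast = fast and hit
    ev = VesicleEvent(
        vesicle_id=trace.vesicle_id, cell_id=trace.cell_id,
        hit=hit, fast_release=fast,
        pre_mean=pre_mean, pre_sd=pre_sd, post_mean=post_mean,
        pre_load=pre_event_load(trace, rna_channel=rna_channel),
    )
    if hit:
        ev.release_magnitude = 1.0 - release_level_at(
            trace, release_at_s, rna_channel=rna_channel)
    if damage_channel in trace.channels:
        ev.galectin_magnitude = float(
            np.max(trace.channels[damage_channel].normalized))
    if normalizer is not None and marker_channel in trace.channels:
        try:
            ev.marker_positive, ev.marker_normalized_mean = \
                classify_marker_positive(trace, normalizer,
                                         marker_channel=marker_channel)
        except ValueError as err:
            logger.warning("marker classification skipped: %s", err)
    return ev


def summarize_cohort(events: list[VesicleEvent]) -> dict:
    """Hit rate, fast-release fraction among hits, release-magnitude summary
    and marker-positive fraction for a cohort of damage events."""
    n = len(events)
    if n == 0:
        raise ValueError("empty cohort")
    hits = [e for e in events if e.hit]
    fast = [e for e in events if e.fast_release]
    out = {
        "n_events": n,
        "hit_rate": len(hits) / n,
        "fast_release_fraction": (len(fast) / len(hits)) if hits else np.nan,
    }
    if fast:
        out["release_magnitude"] = release_magnitude_summary(events)
    scored = [e for e in events if e.marker_positive is not None]
    if scored:
        out["marker_positive_fraction"] = (
            sum(e.marker_positive for e in scored) / len(scored))
    return out
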