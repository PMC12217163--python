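"""Release classification rules, marker positivity and cohort summaries."""

import numpy as np
import pytest

from lnptrace import (
    MarkerNormalizer,
    VesicleEvent,
    classify_fast_release,
    classify_hit,
    classify_marker_positive,
    release_magnitude_summary,
    subgroup_by_load,
    summarize_cohort,
)
from lnptrace.events import median_ci, subgroup_by_galectin_response
from lnptrace.traces import TraceSeries, ChannelTrace


def make_trace(normalized, *, corrected=None, background_sd=None,
               t0_frame=20, dt=2.2, channel="rna", vesicle_id=0, cell_id=1,
               extra_channels=None):
    """Synthetic TraceSeries with given per-frame values (frame 0..n-1)."""
    n = len(normalized)
    frames = np.arange(n)
    normalized = np.asarray(normalized, dtype=float)
    corrected = (np.asarray(corrected, float) if corrected is not None
                 else normalized.copy())
    background_sd = (np.asarray(background_sd, float)
                     if background_sd is not None else np.zeros(n))
    ts = TraceSeries(
        vesicle_id=vesicle_id, cell_id=cell_id, frames=frames,
        times_s=(frames - t0_frame) * dt, t0_frame=t0_frame,
        frame_interval_s=dt, x_px=np.zeros(n), y_px=np.zeros(n),
        z_index=np.zeros(n),
    )
    ts.channels[channel] = ChannelTrace(
        raw_mean=corrected.copy(), local_background=np.zeros(n),
        background_sd=background_sd, corrected=corrected,
        bleach_corrected=corrected.copy(), normalized=normalized,
    )
    for name, values in (extra_channels or {}).items():
        v = np.asarray(values, dtype=float)
        ts.channels[name] = ChannelTrace(
            raw_mean=v.copy(), local_background=np.zeros(n),
            background_sd=np.zeros(n), corrected=v.copy(),
            bleach_corrected=v.copy(), normalized=v.copy(),
        )
    return ts


def step_trace(pre_level, post_level, noise_sd=0.0, seed=0, n=44, t0=22):
    rng = np.random.default_rng(seed)
    v = np.where(np.arange(n) < t0, pre_level, post_level).astype(float)
    v += rng.normal(0, noise_sd, n)
    return make_trace(v, t0_frame=t0)


class TestFastRelease:
    def test_clear_drop_is_flagged(self):
        tr = step_trace(1.0, 0.70, noise_sd=0.05, seed=1)
        flag, pre_mean, pre_sd, post_mean = classify_fast_release(tr)
        assert flag and post_mean < pre_mean - pre_sd

    def test_small_drop_is_not_flagged(self):
        tr = step_trace(1.0, 0.97, noise_sd=0.05, seed=2)
        flag, *_ = classify_fast_release(tr)
        assert not flag

    def test_sensitivity_and_specificity_on_synthetic_cohort(self):
        """Release magnitude 0.25 at noise sd 0.03: >= 95% of releasers and
        <= 5% of non-releasers flagged over 200 traces."""
        flags_rel, flags_non = [], []
        for i in range(100):
            flags_rel.append(classify_fast_release(
                step_trace(1.0, 0.75, noise_sd=0.03, seed=1000 + i))[0])
            flags_non.append(classify_fast_release(
                step_trace(1.0, 1.0, noise_sd=0.03, seed=2000 + i))[0])
        assert np.mean(flags_rel) >= 0.95
        assert np.mean(flags_non) <= 0.05

    def test_scale_invariance(self):
        """Multiplying the raw trace by any positive constant does not change
        the call, because normalization cancels the scale."""
        rng = np.random.default_rng(3)
        raw = np.where(np.arange(44) < 22, 200.0, 160.0) + rng.normal(0, 5, 44)
        for scale in (1.0, 0.01, 37.5):
            v = raw * scale
            norm = v / v[:22].mean()
            tr = make_trace(norm)
            flags = classify_fast_release(tr)
            if scale == 1.0:
                reference = flags[0]
            assert flags[0] == reference

    def test_window_too_small_rejected(self):
        tr = make_trace(np.ones(6), t0_frame=5)
        with pytest.raises(ValueError, match="2 frames"):
            classify_fast_release(tr)


class TestHit:
    def test_strong_spot_detected(self):
        tr = make_trace(np.ones(44), corrected=np.full(44, 200.0),
                        background_sd=np.full(44, 10.0))
        assert classify_hit(tr)

    def test_empty_vesicle_not_detected(self):
        rng = np.random.default_rng(4)
        tr = make_trace(np.ones(44), corrected=rng.normal(0, 4, 44),
                        background_sd=np.full(44, 10.0))
        assert not classify_hit(tr)

    def test_monotone_in_detection_k(self):
        rng = np.random.default_rng(5)
        traces = [make_trace(np.ones(44),
                             corrected=rng.normal(30, 10, 44),
                             background_sd=np.full(44, 10.0),
                             vesicle_id=i) for i in range(40)]
        rates = [np.mean([classify_hit(t, detection_k=k) for t in traces])
                 for k in (0.5, 1, 2, 3, 5, 8)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestReleaseMagnitude:
    def test_identical_drops_give_zero_width_ci(self):
        events = [VesicleEvent(vesicle_id=i, hit=True, fast_release=True,
                               release_magnitude=0.24) for i in range(20)]
        out = release_magnitude_summary(events)
        assert out["median"] == pytest.approx(0.24)
        assert out["ci_low"] == out["ci_high"] == pytest.approx(0.24)

    def test_single_event_gives_point_estimate_only(self):
        events = [VesicleEvent(vesicle_id=0, hit=True, fast_release=True,
                               release_magnitude=0.3)]
        with pytest.warns(UserWarning, match="CI of the median omitted"):
            out = release_magnitude_summary(events)
        assert out["median"] == pytest.approx(0.3)
        assert out["ci_low"] is None

    def test_median_ci_coverage(self):
        """Order-statistic 95% CI covers the true median in >= 90/100
        seeded replicates (n=40 noisy drops around 0.25)."""
        rng = np.random.default_rng(6)
        covered = 0
        for _ in range(100):
            drops = 0.25 + rng.normal(0, 0.05, 40)
            lo, hi = median_ci(drops)
            covered += lo <= 0.25 <= hi
        assert covered >= 90


class TestMarkerPositivity:
    def norm(self):
        return MarkerNormalizer(cell_id=1, p90_start=200.0, p90_end=400.0,
                                t_start_s=0.0, t_end_s=3600.0)

    def test_high_marker_positive(self):
        tr = make_trace(np.ones(44), extra_channels={"marker": np.full(44, 300.0)})
        # p90(t) around t0=22*2.2 s is ~202.7; 300/202.7 > 0.5
        flag, mean = classify_marker_positive(tr, self.norm())
        assert flag

    def test_exactly_half_is_negative(self):
        """The threshold is a strict inequality at 0.5."""
        normalizer = MarkerNormalizer(cell_id=1, p90_start=100.0,
                                      p90_end=100.0, t_start_s=0.0,
                                      t_end_s=3600.0)
        tr = make_trace(np.ones(44), extra_channels={"marker": np.full(44, 50.0)})
        flag, mean = classify_marker_positive(tr, normalizer)
        assert mean == pytest.approx(0.5)
        assert not flag

    def test_linear_p90_interpolation(self):
        """p90 200 at t=0 and 400 at t=3600 s gives p90(1800)=300; a raw
        marker intensity of 165 normalizes to 0.55 -> positive."""
        dt = 18.0  # frame interval such that t0=100 frames -> t=1800 s
        n, t0 = 201, 100
        tr = make_trace(np.ones(n), t0_frame=t0, dt=dt,
                        extra_channels={"marker": np.full(n, 165.0)})
        flag, mean = classify_marker_positive(tr, self.norm())
        assert mean == pytest.approx(0.55, abs=1e-3)
        assert flag

    def test_invalid_normalizer_excludes_event(self):
        bad = MarkerNormalizer(cell_id=2, p90_start=100.0, p90_end=-50.0,
                               t_start_s=0.0, t_end_s=3600.0)
        tr = make_trace(np.ones(44), extra_channels={"marker": np.ones(44)})
        with pytest.raises(ValueError, match="excluded"):
            classify_marker_positive(tr, bad)


class TestSubgrouping:
    def test_nine_distinct_loads_split_evenly(self):
        events = [VesicleEvent(vesicle_id=i, hit=True, pre_load=float(i))
                  for i in range(9)]
        labels = subgroup_by_load(events)
        assert np.bincount(labels).tolist() == [3, 3, 3]
        # ordering follows the load
        assert (np.argsort([e.pre_load for e in events])[:3] ==
                np.where(labels == 0)[0]).all()

    def test_equal_loads_all_low_with_warning(self):
        events = [VesicleEvent(vesicle_id=i, hit=True, pre_load=5.0)
                  for i in range(6)]
        with pytest.warns(UserWarning, match="low group"):
            labels = subgroup_by_load(events)
        assert (labels == 0).all()


class TestInvariants:
    def test_fast_release_implies_hit(self):
        with pytest.raises(ValueError, match="implies hit"):
            VesicleEvent(vesicle_id=0, hit=False, fast_release=True)

    def test_cohort_summary_fields(self):
        events = [VesicleEvent(vesicle_id=i, hit=i % 2 == 0,
                               fast_release=(i % 4 == 0),
                               release_magnitude=0.2 if i % 4 == 0 else np.nan)
                  for i in range(20)]
        s = summarize_cohort(events)
        assert s["hit_rate"] == pytest.approx(0.5)
        assert s["fast_release_fraction"] == pytest.approx(0.5)


class TestGalectinSubgroup:
    def test_median_split_weak_strong(self):
        events = [VesicleEvent(vesicle_id=i, hit=True,
                               galectin_magnitude=float(i)) for i in range(6)]
        labels = subgroup_by_galectin_response(events)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]
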