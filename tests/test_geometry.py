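"""Spot sizing, nuclear distances, sub-endosomal vectors and the random null."""

import math

import numpy as np
import pandas as pd
import pytest

from lnptrace import (
    FWHM_FACTOR,
    simulate_endosome_scene,
    fit_gaussian2d,
    nuclear_distance_normalized,
    endosome_center,
    find_local_maxima,
    pair_and_measure,
    measure_endosome_geometry,
    angular_null,
    angular_difference,
)
from lnptrace.geometry import LocalMaximum
from lnptrace.simulate import render_gaussian_spot


def gaussian_roi(sigma_px, amplitude=1000.0, offset=100.0, size=40,
                 center=None, noise_rng=None):
    img = np.full((size, size), offset)
    cy, cx = center or ((size - 1) / 2, (size - 1) / 2)
    render_gaussian_spot(img, cy, cx, amplitude, sigma_px, patch_radius=size)
    if noise_rng is not None:
        img = noise_rng.poisson(img).astype(float)
    return img


class TestSpotFit:
    def test_fwhm_closed_form_on_noiseless_gaussian(self):
        """sigma = 100 nm at 20 nm pixels: FWHM = 2 sqrt(2 ln2) x 100 nm."""
        fit = fit_gaussian2d(gaussian_roi(sigma_px=5.0), pixel_size_nm=20.0)
        assert fit.converged
        assert fit.sigma_x_nm == pytest.approx(100.0, abs=1e-3)
        assert fit.fwhm_nm == pytest.approx(235.48, abs=0.01)

    def test_fwhm_sigma_relation_exact_for_any_fit(self):
        fit = fit_gaussian2d(gaussian_roi(3.0, center=(17.3, 21.8)), 46.0)
        assert fit.fwhm_nm == FWHM_FACTOR * 0.5 * (fit.sigma_x_nm + fit.sigma_y_nm)

    def test_noisy_fwhm_within_five_percent(self):
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            fit = fit_gaussian2d(gaussian_roi(3.0, amplitude=2000.0,
                                              noise_rng=rng), 46.0)
            assert fit.converged
            errs.append(abs(fit.fwhm_nm - FWHM_FACTOR * 3.0 * 46.0)
                        / (FWHM_FACTOR * 3.0 * 46.0))
        assert np.median(errs) < 0.05

    def test_flat_roi_flagged_not_crashed(self):
        fit = fit_gaussian2d(np.full((30, 30), 55.0), 46.0)
        assert not fit.converged


class TestNuclearDistance:
    def foci(self, dists, cell=1, channel="a"):
        return pd.DataFrame([{"cell_id": cell, "channel": channel,
                              "x_px": d, "y_px": 0.0} for d in dists])

    def test_min_mid_max_map_to_0_half_1(self):
        out, _ = nuclear_distance_normalized(self.foci([2, 5, 8]),
                                             {1: (0.0, 0.0)})
        assert np.allclose(sorted(out.d_norm), [0.0, 0.5, 1.0])

    def test_single_focus_cell_excluded(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            out, _ = nuclear_distance_normalized(self.foci([4]), {1: (0, 0)})
        assert len(out) == 0

    def test_zero_spread_cell_excluded(self):
        with pytest.warns(UserWarning, match="zero distance spread"):
            out, _ = nuclear_distance_normalized(self.foci([4, 4]), {1: (0, 0)})
        assert len(out) == 0

    def test_inner_channel_has_smaller_mean(self):
        """A channel placed closer to the nucleus (disintegrated particles)
        has the smaller mean normalized distance."""
        rng = np.random.default_rng(7)
        rows = []
        for cell in (1, 2, 3):
            for d in rng.uniform(2, 10, 8):
                rows.append({"cell_id": cell, "channel": "inner",
                             "x_px": d, "y_px": 0.0})
            for d in rng.uniform(8, 25, 8):
                rows.append({"cell_id": cell, "channel": "outer",
                             "x_px": d, "y_px": 0.0})
        _, means = nuclear_distance_normalized(
            pd.DataFrame(rows), {c: (0.0, 0.0) for c in (1, 2, 3)})
        piv = means.pivot(index="cell_id", columns="channel",
                          values="mean_d_norm")
        assert (piv["inner"] < piv["outer"]).all()


class TestEndosomeCenter:
    def annulus(self, size=21, r=6):
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        rr = np.hypot(yy - c, xx - c)
        mask = rr <= r + 2
        ring = np.exp(-((rr - r) ** 2) / 2.0)
        return mask, ring, c

    def test_symmetric_annulus_centers_geometrically(self):
        mask, ring, c = self.annulus()
        x, y = endosome_center(mask, ring)
        assert (x, y) == pytest.approx((c, c), abs=1e-9)

    def test_bright_arc_pulls_weighted_centroid(self):
        mask, ring, c = self.annulus()
        ring[:, int(c) + 3:] *= 5.0          # bright arc on the right
        x, y = endosome_center(mask, ring)
        assert x > c + 0.5

    def test_unweighted_ignores_intensity(self):
        mask, ring, c = self.annulus()
        ring[:, int(c) + 3:] *= 5.0
        x, y = endosome_center(mask, ring, weighted=False)
        assert (x, y) == pytest.approx((c, c), abs=1e-9)


class TestLocalMaxima:
    def scene(self, angles, r=8.0, size=40):
        img = np.full((size, size), 100.0)
        c = (size - 1) / 2
        for a in angles:
            render_gaussian_spot(img, c + r * math.sin(math.radians(a)),
                                 c + r * math.cos(math.radians(a)), 400.0, 1.4)
        yy, xx = np.mgrid[0:size, 0:size]
        mask = np.hypot(yy - c, xx - c) <= r + 4
        return img, mask, c

    def test_single_spot_found_at_programmed_angle(self):
        img, mask, c = self.scene([40.0])
        maxima = find_local_maxima(img, mask)
        assert len(maxima) == 1
        ang = math.degrees(math.atan2(maxima[0].y_px - c,
                                      maxima[0].x_px - c)) % 360
        assert ang == pytest.approx(40.0, abs=3.0)

    def test_two_separated_spots_found(self):
        img, mask, c = self.scene([10.0, 170.0])
        maxima = find_local_maxima(img, mask)
        assert len(maxima) == 2

    def test_uniform_ring_yields_no_maxima(self):
        size = 40
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        rr = np.hypot(yy - c, xx - c)
        img = np.where((rr >= 6) & (rr <= 8), 200.0, 200.0)  # flat inside mask
        mask = rr <= 10
        assert find_local_maxima(img, mask) == []


class TestPairing:
    def mk(self, angle, radius=10.0, center=(20.0, 20.0)):
        return LocalMaximum(
            x_px=center[0] + radius * math.cos(math.radians(angle)),
            y_px=center[1] + radius * math.sin(math.radians(angle)),
            intensity=1.0)

    def test_circular_fold(self):
        pairs = pair_and_measure((20.0, 20.0), [self.mk(350)], [self.mk(10)],
                                 pixel_size_nm=46.0)
        assert pairs[0].angular_difference_deg == pytest.approx(20.0, abs=1e-6)

    def test_magnitude_difference_in_nm(self):
        pairs = pair_and_measure((20.0, 20.0), [self.mk(0, radius=10)],
                                 [self.mk(0, radius=8)], pixel_size_nm=46.0)
        assert pairs[0].magnitude_difference_nm == pytest.approx(92.0, abs=1e-6)

    def test_assignment_minimizes_total_angle(self):
        """Marker maxima {0, 180} vs LNP {10, 170}: the (0-10),(180-170)
        assignment (total 20 deg) beats the crossed one (total 340 deg)."""
        pairs = pair_and_measure((20.0, 20.0),
                                 [self.mk(0), self.mk(180)],
                                 [self.mk(10), self.mk(170)], 46.0)
        diffs = sorted(p.angular_difference_deg for p in pairs)
        assert diffs == pytest.approx([10.0, 10.0], abs=1e-6)

    def test_empty_channel_gives_no_pairs(self):
        assert pair_and_measure((0, 0), [], [self.mk(0)], 46.0) == []


class TestAngularDifference:
    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(8)
        a, b = rng.uniform(0, 720, 200), rng.uniform(-360, 360, 200)
        d1, d2 = angular_difference(a, b), angular_difference(b, a)
        assert np.allclose(d1, d2)
        assert (d1 >= 0).all() and (d1 <= 180).all()

    def test_triangle_like_bound(self):
        rng = np.random.default_rng(9)
        u, v, w = (rng.uniform(0, 360, 500) for _ in range(3))
        assert (angular_difference(u, w) <=
                angular_difference(u, v) + angular_difference(v, w) + 1e-9).all()

    def test_enumerated_differences(self):
        pairs = [(0, 90), (10, 350), (180, 180)]
        diffs = [angular_difference(a, b) for a, b in pairs]
        assert diffs == pytest.approx([90.0, 20.0, 0.0])
        assert np.mean(diffs) == pytest.approx(36.667, abs=1e-3)


class TestNull:
    def test_single_null_uniform_with_mean_90(self):
        mean, diffs = angular_null(20_000, "single", rng_seed=1)
        se = diffs.std() / math.sqrt(len(diffs))
        assert abs(mean - 90.0) < 3 * se
        # uniformity on [0, 180]: compare the empirical CDF on a grid
        grid = np.linspace(0, 180, 19)
        ecdf = np.searchsorted(np.sort(diffs), grid) / len(diffs)
        assert np.abs(ecdf - grid / 180.0).max() < 0.02

    def test_dual_antipodal_null_mean_45(self):
        mean, diffs = angular_null(20_000, "dual_antipodal", rng_seed=2)
        se = diffs.std() / math.sqrt(len(diffs) / 2)  # pairs are duplicated
        assert abs(mean - 45.0) < 3 * se
        assert diffs.max() <= 90.0

    def test_dual_construction_by_grid_enumeration(self):
        """Brute force over a fine deterministic grid of rotations: the
        nearest-angle matched difference of two antipodal doublets averages
        exactly 45 deg."""
        delta = np.linspace(0, 180, 3601, endpoint=False)
        matched = np.minimum(np.minimum(delta, 360 - delta),
                             180 - np.minimum(delta, 360 - delta))
        assert matched.mean() == pytest.approx(45.0, abs=0.05)


class TestSceneRecovery:
    def test_fixed_offset_scene_recovered(self):
        """Damage foci placed 20 deg from the LNP foci: the measured median
        angular difference lands on 20 deg (noiseless scene)."""
        stack, masks, truth = simulate_endosome_scene(
            25, angle_offset_deg=20.0, rng_seed=5)
        table = measure_endosome_geometry(stack, masks)
        assert len(table) >= 20
        assert np.median(table.angular_difference_deg) == pytest.approx(
            20.0, abs=1.5)

    def test_zero_offset_scene_measures_zero(self):
        stack, masks, _ = simulate_endosome_scene(
            10, angle_offset_deg=0.0, rng_seed=6)
        table = measure_endosome_geometry(stack, masks)
        assert np.median(table.angular_difference_deg) < 2.0


    def test_dual_independent_mode_provided(self):
        """The alternative two-independent-maxima null runs and differs from
        the antipodal construction."""
        mean, diffs = angular_null(20_000, "dual_independent", rng_seed=3)
        assert diffs.shape == (40_000,)
        assert 0 <= mean <= 180
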