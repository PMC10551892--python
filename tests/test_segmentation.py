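"""Histogram segmentation: inflexion point, Gaussian fit, CI thresholds."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vesselvox import (
    PhantomSpec,
    binarize,
    ci_threshold,
    compute_histogram,
    find_inflexion_threshold,
    fit_background_gaussian,
    partial_volume_ratio,
    threshold_sensitivity,
)
from vesselvox.phantom import region_labels
from vesselvox.segmentation import (
    GaussianFitResult,
    GrayHistogram,
    InflexionError,
    SegmentationError,
    auto_fit_range,
)
from vesselvox.volio import BinaryMask, Volume3D


def hist_from_samples(samples: np.ndarray, bit_depth: int = 8) -> GrayHistogram:
    vals = np.clip(np.rint(samples), 0, 2**bit_depth - 1).astype(
        np.uint8 if bit_depth == 8 else np.uint16
    )
    shape = (1, 1, vals.size)
    return compute_histogram(Volume3D(vals.reshape(shape), (1, 1, 1), bit_depth))


class TestHistogram:
    def test_constant_volume_single_bin(self):
        vol = Volume3D(np.full((10, 10, 10), 7, dtype=np.uint8), (1, 1, 1), 8)
        h = compute_histogram(vol)
        assert h.counts[7] == 1000
        assert h.counts.sum() == 1000
        assert np.flatnonzero(h.counts).tolist() == [7]

    def test_counts_match_exhaustive_tally(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 256, size=(7, 8, 9), dtype=np.uint8)
        h = compute_histogram(Volume3D(vals, (1, 1, 1), 8))
        tally = Counter(int(v) for v in vals.ravel())
        for g, c in tally.items():
            assert h.counts[g] == c
        assert h.counts.sum() == vals.size

    def test_mask_restriction_counts_only_in_mask(self):
        vals = np.zeros((4, 4, 4), dtype=np.uint8)
        vals[0] = 9
        vol = Volume3D(vals, (1, 1, 1), 8)
        mask = BinaryMask(vals == 9, (1, 1, 1))
        h = compute_histogram(vol, within=mask)
        assert h.source_voxel_count == 16
        assert h.counts[9] == 16

    def test_empty_mask_rejected(self):
        vol = Volume3D(np.zeros((2, 2, 2), dtype=np.uint8), (1, 1, 1), 8)
        with pytest.raises(SegmentationError, match="empty"):
            compute_histogram(vol, within=BinaryMask(np.zeros((2, 2, 2), bool), (1, 1, 1)))

    def test_phantom_histogram_has_three_modes(self, capillary_volume):
        from scipy.ndimage import gaussian_filter1d
        from scipy.signal import find_peaks

        h = compute_histogram(capillary_volume)
        smooth = gaussian_filter1d(h.counts.astype(float), 2.0)
        peaks, _ = find_peaks(smooth, prominence=0.002 * smooth.max())
        # non-tissue (~10), tissue (~60) and vessel (~220) populations
        assert any(p < 30 for p in peaks)
        assert any(40 < p < 90 for p in peaks)
        assert any(p > 180 for p in peaks)


class TestInflexion:
    def test_threshold_separates_two_well_split_gaussians(self):
        """Oracle: the inflexion must sit between the modes, at or above the
        histogram valley, and split the two populations nearly perfectly."""
        rng = np.random.default_rng(42)
        lo = rng.normal(20, 5, 500_000)
        hi = rng.normal(120, 5, 500_000)
        h = hist_from_samples(np.concatenate([lo, hi]))
        t = find_inflexion_threshold(h)
        assert 20 < t < 120
        assert 40 <= t <= 105  # between the modes, on the rising flank
        assert (lo < t).mean() > 0.999
        assert (hi >= t).mean() > 0.99

    def test_single_mode_histogram_rejected(self):
        rng = np.random.default_rng(1)
        h = hist_from_samples(rng.normal(100, 8, 100_000))
        with pytest.raises(InflexionError) as err:
            find_inflexion_threshold(h)
        assert err.value.histogram is h  # diagnostic dump attached

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        samples = np.concatenate([rng.normal(15, 4, 200_000), rng.normal(90, 9, 200_000)])
        h = hist_from_samples(samples)
        assert find_inflexion_threshold(h) == find_inflexion_threshold(h)

    def test_phantom_nontissue_falls_below_threshold(
        self, capillary_spec, capillary_volume
    ):
        h = compute_histogram(capillary_volume)
        t = find_inflexion_threshold(h)
        labels = region_labels(capillary_spec)
        nontissue = capillary_volume.values[labels == 0]
        assert (nontissue < t).mean() >= 0.99


class TestGaussianFit:
    def test_recovers_parameters_from_sampled_histogram(self):
        rng = np.random.default_rng(5)
        h = hist_from_samples(rng.normal(100, 8, 1_000_000))
        fit = fit_background_gaussian(h, (60, 140))
        assert fit.mean == pytest.approx(100, abs=0.2)
        assert fit.sd == pytest.approx(8, abs=0.2)
        assert fit.r_squared > 0.99

    def test_exact_curve_fits_perfectly(self):
        g = np.arange(256)
        counts = np.rint(5000 * np.exp(-((g - 80.0) ** 2) / (2 * 36.0))).astype(int)
        h = GrayHistogram(g, counts, int(counts.sum()))
        fit = fit_background_gaussian(h, (40, 120))
        assert fit.r_squared > 0.9999
        assert fit.mean == pytest.approx(80, abs=0.05)
        assert fit.sd == pytest.approx(6, abs=0.05)

    def test_phantom_background_recovered_within_2pct(
        self, capillary_spec, capillary_volume
    ):
        h = compute_histogram(capillary_volume)
        t = find_inflexion_threshold(h)
        oos = binarize(capillary_volume, t)
        h2 = compute_histogram(capillary_volume, within=oos)
        fit = fit_background_gaussian(h2, auto_fit_range(h2, t))
        mu, sd = capillary_spec.background_gray
        assert fit.mean == pytest.approx(mu, rel=0.02)
        assert fit.sd == pytest.approx(sd, rel=0.02)

    def test_too_narrow_range_rejected(self):
        rng = np.random.default_rng(6)
        h = hist_from_samples(rng.normal(100, 8, 10_000))
        from vesselvox.segmentation import GaussianFitError

        with pytest.raises(GaussianFitError, match="bins"):
            fit_background_gaussian(h, (100, 104))


class TestCiThreshold:
    def test_alpha_005_gives_z_196(self):
        fit = GaussianFitResult(mean=0, sd=1, amplitude=1, r_squared=1, fit_range=(0, 1))
        dec = ci_threshold(fit, 0.05, "upper")
        assert round(dec.z_crit, 2) == 1.96

    def test_upper_threshold_arithmetic(self):
        fit = GaussianFitResult(mean=100, sd=8, amplitude=1, r_squared=1, fit_range=(0, 1))
        dec = ci_threshold(fit, 0.05, "upper")
        assert dec.threshold == pytest.approx(115.68, abs=0.01)
        low = ci_threshold(fit, 0.05, "lower")
        assert low.threshold == pytest.approx(84.32, abs=0.01)

    def test_alpha_to_one_collapses_to_mean(self):
        fit = GaussianFitResult(mean=50, sd=4, amplitude=1, r_squared=1, fit_range=(0, 1))
        dec = ci_threshold(fit, 0.999999, "upper")
        assert dec.z_crit == pytest.approx(0.0, abs=1e-4)
        assert dec.threshold == pytest.approx(50.0, abs=1e-3)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_invalid_alpha_rejected(self, alpha):
        fit = GaussianFitResult(mean=0, sd=1, amplitude=1, r_squared=1, fit_range=(0, 1))
        with pytest.raises(SegmentationError):
            ci_threshold(fit, alpha)


class TestBinarize:
    def test_threshold_zero_selects_everything(self):
        vol = Volume3D(np.random.default_rng(0).integers(0, 256, (5, 5, 5), dtype=np.uint8).astype(np.uint8), (1, 1, 1), 8)
        assert binarize(vol, 0).count() == 125

    def test_threshold_above_max_selects_nothing(self):
        vol = Volume3D(np.full((5, 5, 5), 255, dtype=np.uint8), (1, 1, 1), 8)
        assert binarize(vol, 256).count() == 0

    @pytest.mark.parametrize("z,expected", [(1.0, stats.norm.cdf(1.0)),
                                            (1.96, stats.norm.cdf(1.96)),
                                            (3.0, stats.norm.cdf(3.0))])
    def test_gaussian_background_exclusion_calibrated(self, z, expected):
        """Fraction excluded at mean + z*sd equals Phi(z) on simulated noise."""
        rng = np.random.default_rng(int(z * 100))
        vals = np.clip(np.rint(rng.normal(10_000, 800, (100, 100, 100))), 0, 65535)
        vol = Volume3D(vals.astype(np.uint16), (1, 1, 1), 16)
        mask = binarize(vol, 10_000 + z * 800)
        excluded = 1 - mask.count() / vol.values.size
        assert excluded == pytest.approx(expected, abs=0.002)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.lists(st.floats(0, 255), min_size=2, max_size=6))
    def test_foreground_monotone_nonincreasing_in_threshold(self, thresholds):
        rng = np.random.default_rng(9)
        vol = Volume3D(rng.integers(0, 256, (8, 8, 8), dtype=np.uint8).astype(np.uint8), (1, 1, 1), 8)
        counts = [binarize(vol, t).count() for t in sorted(thresholds)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPartialVolumeModel:
    def test_ratio_is_one_when_radius_twice_voxel(self):
        assert partial_volume_ratio(10, 2, 1).surface_to_volume_ratio == 1.0

    def test_reference_cylinder_values(self):
        m = partial_volume_ratio(100, 5, 1)
        assert m.nv_volume == pytest.approx(7853.98, abs=0.01)
        assert m.nv_surface == pytest.approx(3141.59, abs=0.01)
        assert m.surface_to_volume_ratio == pytest.approx(0.4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(1, 1e3), st.floats(0.5, 50), st.floats(0.1, 5)
    )
    def test_ratio_independent_of_length_and_inverse_in_radius(self, L, r, d):
        m = partial_volume_ratio(L, r, d)
        assert m.surface_to_volume_ratio == pytest.approx(2 * d / r)
        doubled = partial_volume_ratio(L, 2 * r, d)
        assert doubled.surface_to_volume_ratio == pytest.approx(m.surface_to_volume_ratio / 2)


class TestThresholdSensitivity:
    def test_zero_delta_reports_zero_change(self, capillary_result):
        res = capillary_result
        table = threshold_sensitivity(
            res.volume, res.oos_mask, res.decision, delta=0.0,
            descriptors=("volume_density",),
        )
        assert (table["pct_change_minus"].abs() < 1e-9).all()
        assert (table["pct_change_plus"].abs() < 1e-9).all()

    def test_sharp_contrast_phantom_is_insensitive(self, capillary_result):
        """With the vessel population far above the threshold, +-1 gray level
        moves only partial-volume voxels: descriptor changes stay small."""
        res = capillary_result
        table = threshold_sensitivity(
            res.volume, res.oos_mask, res.decision, delta=1.0,
            descriptors=("volume_density", "total_length"),
        ).set_index("descriptor")
        assert abs(table.loc["volume_density", "pct_change_plus"]) < 5
        assert abs(table.loc["volume_density", "pct_change_minus"]) < 5
        assert abs(table.loc["total_length", "pct_change_plus"]) < 5

    def test_density_change_sign_consistent(self, capillary_result):
        """Raising the threshold can only shrink the vessel mask."""
        res = capillary_result
        table = threshold_sensitivity(
            res.volume, res.oos_mask, res.decision, delta=3.0,
            descriptors=("volume_density",),
        ).set_index("descriptor")
        assert table.loc["volume_density", "pct_change_plus"] <= 0
        assert table.loc["volume_density", "pct_change_minus"] >= 0
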