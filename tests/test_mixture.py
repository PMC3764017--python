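"""Histogramming, Gaussian decomposition and subpopulation classification."""

import numpy as np
import pandas as pd
import pytest

from nmjquant import (
    build_histogram,
    classify_fibers,
    fit_gaussian,
    fit_two_gaussians,
    r_squared,
    select_model,
    validate_grouping,
)
from nmjquant.mixture import GaussFit, MixtureFit, _gauss


def band_sample(rng, means, sds, weights, n):
    """Mixture sample restricted to the detection band [0.2, 1.0)."""
    comp = rng.choice(len(means), size=3 * n, p=weights)
    x = rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])
    x = x[(x >= 0.2) & (x < 1.0)]
    return x[:n]


class TestHistogram:
    def test_single_value_occupies_one_bin(self):
        h = build_histogram(np.full(10, 0.55), bin_width=0.05)
        assert h.counts.sum() == 10
        assert np.count_nonzero(h.counts) == 1

    def test_count_conservation_on_large_pool(self):
        rng = np.random.default_rng(0)
        amps = band_sample(rng, [0.55], [0.16], [1.0], 2785)
        h = build_histogram(amps)
        assert h.n_total == 2785
        assert h.counts.sum() == 2785

    def test_boundary_value_goes_to_upper_bin(self):
        h = build_histogram(np.array([0.25]), bin_width=0.05)
        # 0.25 sits on the edge between [0.20,0.25) and [0.25,0.30)
        assert h.counts[1] == 1 and h.counts[0] == 0

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            build_histogram(np.array([]))
        with pytest.raises(ValueError):
            build_histogram(np.array([0.5]), bin_width=0.0)
        with pytest.raises(ValueError):
            build_histogram(np.array([1.5]))


class TestRSquared:
    def test_perfect_and_null_fits(self):
        obs = np.array([1.0, 4.0, 2.0])
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_three_bin_long_hand_case(self):
        obs = np.array([2.0, 5.0, 3.0])
        fit = np.array([2.5, 4.5, 3.5])
        # by hand: SS_res = 0.25+0.25+0.25 = 0.75; mean=10/3;
        # SS_tot = (2-10/3)^2+(5-10/3)^2+(3-10/3)^2 = 16/9+25/9+1/9 = 42/9
        assert r_squared(obs, fit) == pytest.approx(1 - 0.75 / (42.0 / 9.0))

    def test_zero_variance_flagged(self):
        assert np.isnan(r_squared(np.full(4, 2.0), np.full(4, 2.0)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            r_squared(np.array([1.0]), np.array([1.0, 2.0]))


class TestGaussianFits:
    def test_exact_gaussian_histogram_recovered(self):
        h = build_histogram(np.linspace(0.2, 0.999, 500))  # placeholder bins
        counts = _gauss(h.centers, 120.0, 0.55, 0.12)
        h.counts = counts
        fit = fit_gaussian(h)
        assert fit.converged
        assert fit.mean == pytest.approx(0.55, abs=1e-6)
        assert fit.width == pytest.approx(0.12, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_two_component_recovery_from_sampled_mixture(self):
        rng = np.random.default_rng(7)
        amps = band_sample(rng, [0.32, 0.64], [0.09, 0.09], [0.5, 0.5], 3000)
        fit = fit_two_gaussians(build_histogram(amps))
        assert fit.converged
        assert fit.means[0] == pytest.approx(0.32, abs=0.03)
        assert fit.means[1] == pytest.approx(0.64, abs=0.03)

    def test_too_few_bins_is_a_clean_failure(self):
        h = build_histogram(np.full(50, 0.55))
        assert not fit_gaussian(h).converged
        assert not fit_two_gaussians(h).converged

    def test_peak_location_stable_under_small_bin_shift(self):
        rng = np.random.default_rng(3)
        amps = band_sample(rng, [0.55], [0.12], [1.0], 4000)
        f1 = fit_gaussian(build_histogram(amps))
        f2 = fit_gaussian(build_histogram(amps + 0.02))  # shift < bin_width/2
        assert f2.mean - f1.mean == pytest.approx(0.02, abs=0.02)


class TestModelSelection:
    def test_identical_fits_stay_unimodal(self):
        s = GaussFit(100.0, 0.5, 0.1, 0.95, True)
        d = MixtureFit((50.0, 50.0), (0.45, 0.55), (0.1, 0.1), 0.95, True)
        assert select_model(s, d) == "unimodal"

    def test_clear_bimodal_structure_detected(self):
        rng = np.random.default_rng(11)
        amps = band_sample(rng, [0.32, 0.64], [0.09, 0.09], [0.45, 0.55], 3500)
        h = build_histogram(amps)
        assert select_model(fit_gaussian(h), fit_two_gaussians(h)) == "bimodal"

    def test_unimodal_sample_not_split(self):
        rng = np.random.default_rng(13)
        amps = band_sample(rng, [0.55], [0.16], [1.0], 3000)
        h = build_histogram(amps)
        assert select_model(fit_gaussian(h), fit_two_gaussians(h)) == "unimodal"

    def test_both_fits_failed_is_undetermined(self):
        bad = GaussFit(np.nan, np.nan, np.nan, np.nan, False)
        badd = MixtureFit((np.nan,) * 2, (np.nan,) * 2, (np.nan,) * 2, np.nan, False)
        assert select_model(bad, badd) == "undetermined"


def fiber_frame(means, ids=None):
    ids = ids or [f"f{k}" for k in range(len(means))]
    return pd.DataFrame({"fiber_id": ids, "mean_mepp": means})


class TestClassification:
    def test_explicit_cutoff_boundaries(self):
        frame = fiber_frame([0.32, 0.64, 0.49])
        got = classify_fibers(frame, cutoff=0.49)
        assert got.labels == {"f0": "A", "f1": "B", "f2": "B"}  # tie goes to B

    def test_default_cutoff_is_cohort_mean(self):
        frame = fiber_frame([0.3, 0.5, 0.7])
        got = classify_fibers(frame)
        assert got.cutoff == pytest.approx(0.5)

    def test_undefined_fiber_left_unassigned(self):
        frame = fiber_frame([0.3, np.nan])
        got = classify_fibers(frame, cutoff=0.49)
        assert got.unassigned == ("f1",)

    def test_reclassification_is_idempotent(self):
        frame = fiber_frame([0.3, 0.45, 0.52, 0.7])
        first = classify_fibers(frame, cutoff=0.49)
        second = classify_fibers(frame, cutoff=first.cutoff)
        assert first.labels == second.labels


class TestGroupingValidation:
    def _fits(self, a, b, p1, p2):
        fa = GaussFit(10.0, a, 0.1, 0.9, True)
        fb = GaussFit(10.0, b, 0.1, 0.9, True)
        pooled = MixtureFit((10.0, 10.0), (p1, p2), (0.1, 0.1), 0.99, True)
        return fa, fb, pooled

    def test_matching_peaks_pass(self):
        assert validate_grouping(*self._fits(0.30, 0.65, 0.31, 0.63)) == "pass"
        assert validate_grouping(*self._fits(0.3, 0.6, 0.3, 0.6)) == "pass"

    def test_displaced_peaks_fail(self):
        assert validate_grouping(*self._fits(0.30, 0.85, 0.31, 0.63)) == "fail"

    def test_failed_fit_is_undetermined(self):
        fa, fb, pooled = self._fits(0.3, 0.6, 0.3, 0.6)
        fa.converged = False
        assert validate_grouping(fa, fb, pooled) == "undetermined"
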