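import numpy as np
import pytest
import scipy.stats
from skimage.metrics import structural_similarity

from paraft import apply
from paraft.metrics import (
    bland_altman_binned,
    correlation_map,
    error_metrics,
    fisher_z_compare,
    fit_gas_model,
    gas_model,
    negative_indicator_map,
    relative_cohens_d,
    relative_residual,
    ssim,
    tscore_map,
)


class TestErrorMetrics:
    def test_perfect_reconstruction(self):
        x = np.arange(9.0).reshape(3, 3) - 2.0
        q = error_metrics(x, x)
        assert q.bias == q.l1 == q.l2 == 0.0
        assert q.n_negative_pixels == int((x < 0).sum())

    def test_constant_offset_closed_forms(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 2, size=(6, 4))
        c = 0.7
        q = error_metrics(x, x - c)
        n = x.size
        assert q.bias == pytest.approx(c, rel=1e-12)
        assert q.l1 == pytest.approx(c, rel=1e-12)
        assert q.l2 == pytest.approx(c / np.sqrt(n), rel=1e-12)

    def test_matches_brute_force_sums(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 5))
        b = rng.normal(size=(5, 5))
        q = error_metrics(a, b)
        e = a - b
        assert q.bias == pytest.approx(sum(e.ravel()) / 25, abs=1e-14)
        assert q.l1 == pytest.approx(sum(abs(v) for v in e.ravel()) / 25, abs=1e-14)
        assert q.l2 == pytest.approx(np.sqrt(sum(v * v for v in e.ravel())) / 25, abs=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_metrics(np.zeros((3, 3)), np.zeros((4, 4)))


class TestSsim:
    def test_self_similarity_is_one(self):
        x = np.random.default_rng(0).uniform(size=(16, 16))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(size=(2, 16, 16))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-14)

    def test_constant_images_closed_form(self):
        mx, my = 0.4, 0.9
        x = np.full((8, 8), mx)
        y = np.full((8, 8), my)
        C1 = 1e-4
        val = ssim(x, y, C1=C1, C2=1e-4, data_range=1.0)
        expected = (2 * mx * my + C1) / (mx * mx + my * my + C1)
        assert val == pytest.approx(expected, rel=1e-9)

    def test_matches_skimage_reference(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(32, 32))
        y = x + rng.normal(0, 0.1, size=(32, 32))
        ref = structural_similarity(x, y, win_size=7, data_range=1.0, gaussian_weights=False)
        assert ssim(x, y, data_range=1.0) == pytest.approx(ref, abs=1e-10)


class TestRelativeResidual:
    def test_exact_solution_zero(self, small_model):
        x = np.random.default_rng(0).uniform(size=small_model.image_shape)
        d = apply(small_model, x)
        assert relative_residual(small_model, x, d) == pytest.approx(0.0, abs=1e-14)

    def test_zero_image_gives_one(self, small_model):
        d = np.ones(small_model.matrix.shape[0])
        assert relative_residual(small_model, np.zeros(small_model.image_shape), d) == 1.0

    def test_matches_direct_norms(self, small_model):
        rng = np.random.default_rng(1)
        x = rng.normal(size=small_model.image_shape)
        d = rng.normal(size=small_model.matrix.shape[0])
        direct = np.linalg.norm(small_model.matrix @ x.ravel() - d) / np.linalg.norm(d)
        assert relative_residual(small_model, x, d) == pytest.approx(direct, rel=1e-12)


class TestNegativeIndicator:
    def test_nonnegative_series_all_zero(self):
        series = [np.abs(np.random.default_rng(k).normal(size=(4, 4))) for k in range(3)]
        assert negative_indicator_map(series).sum() == 0

    def test_single_negative_pixel_counted_once(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        b[1, 2] = -0.5
        out = negative_indicator_map([a, b])
        assert out[1, 2] == 1 and out.sum() == 1


class TestBlandAltman:
    def test_identical_inputs_mass_on_zero_difference(self):
        a = np.random.default_rng(0).uniform(size=(50, 50))
        r = bland_altman_binned(a, a, n_bins=10, sample_frac=0.5, seed=1)
        assert r.mean_difference == 0.0
        assert r.loa_low == r.loa_high == 0.0

    def test_constant_offset(self):
        a = np.random.default_rng(1).uniform(size=1000)
        r = bland_altman_binned(a + 0.3, a, n_bins=10, sample_frac=1.0, seed=0)
        assert r.mean_difference == pytest.approx(0.3, rel=1e-12)
        assert r.loa_high - r.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_seeded_histogram_reproducible(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 2000))
        r1 = bland_altman_binned(a, b, n_bins=20, sample_frac=0.1, seed=9)
        r2 = bland_altman_binned(a, b, n_bins=20, sample_frac=0.1, seed=9)
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_binned(np.ones(5), np.ones(5), sample_frac=0.01)


class TestTscore:
    def test_identical_stacks_zero(self):
        s = [np.random.default_rng(k).normal(size=(3, 3)) for k in range(4)]
        t = tscore_map(s, s)
        np.testing.assert_array_equal(t, np.zeros((3, 3)))

    def test_zero_variance_shift_flagged_infinite(self):
        before = [np.zeros((2, 2))] * 3
        after = [np.ones((2, 2))] * 3
        t = tscore_map(before, after)
        assert np.all(np.isinf(t)) and np.all(t > 0)

    def test_matches_welch_formula_and_scipy(self):
        rng = np.random.default_rng(3)
        before = rng.normal(0, 1, size=(20, 4, 4))
        after = rng.normal(0.5, 2, size=(30, 4, 4))
        t = tscore_map(before, after)
        ref = scipy.stats.ttest_ind(after, before, axis=0, equal_var=False).statistic
        np.testing.assert_allclose(t, ref, rtol=1e-10)

    def test_single_frame_stack_rejected(self):
        with pytest.raises(ValueError):
            tscore_map([np.zeros((2, 2))], [np.zeros((2, 2))] * 3)


class TestRelativeCohensD:
    def test_equal_transitions_give_unity(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1, size=(40, 3, 3))
        a = rng.normal(1, 1, size=(40, 3, 3))
        out = relative_cohens_d(b, a, b, a)
        np.testing.assert_allclose(out, 1.0, rtol=1e-12)

    def test_no_drug_effect_is_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2, 2))
        gas_b = rng.normal(0, 1, size=(30, 2, 2))
        gas_a = rng.normal(2, 1, size=(30, 2, 2))
        out = relative_cohens_d(x, x, gas_b, gas_a)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        db = rng.normal(0, 1, size=(25, 2, 2))
        da = rng.normal(0.8, 1.3, size=(35, 2, 2))
        gb = rng.normal(0, 1, size=(25, 2, 2))
        ga = rng.normal(1.5, 0.7, size=(35, 2, 2))

        def cohend(x, y):
            n1, n2 = x.shape[0], y.shape[0]
            sp = np.sqrt(
                ((n1 - 1) * x.var(axis=0, ddof=1) + (n2 - 1) * y.var(axis=0, ddof=1))
                / (n1 + n2 - 2)
            )
            return (y.mean(axis=0) - x.mean(axis=0)) / sp

        expected = cohend(db, da) / cohend(gb, ga)
        np.testing.assert_allclose(relative_cohens_d(db, da, gb, ga), expected, rtol=1e-10)


class TestCorrelationMap:
    def test_affine_function_of_waveform_is_one(self):
        w = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
        series = [np.full((2, 2), 3.0 * v + 1.0) for v in w]
        np.testing.assert_allclose(correlation_map(series, w), 1.0, rtol=1e-12)

    def test_negated_waveform_is_minus_one(self):
        w = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        series = [np.full((2, 2), -v) for v in w]
        np.testing.assert_allclose(correlation_map(series, w), -1.0, rtol=1e-12)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=40)
        series = [rng.normal(size=(3, 3)) for _ in range(40)]
        out = correlation_map(series, w)
        stack = np.stack(series)
        for iy in range(3):
            for ix in range(3):
                ref = scipy.stats.pearsonr(stack[:, iy, ix], w).statistic
                assert out[iy, ix] == pytest.approx(ref, abs=1e-12)

    def test_constant_pixel_flagged(self):
        w = np.array([0.0, 1.0, 0.0, 1.0])
        series = [np.zeros((2, 2)) for _ in w]
        assert np.all(np.isnan(correlation_map(series, w)))


class TestFisherZ:
    def test_equal_correlations_give_null(self):
        z, p = fisher_z_compare(0.4, 50, 0.4, 80)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric(self):
        z1, _ = fisher_z_compare(0.5, 40, 0.2, 60)
        z2, _ = fisher_z_compare(0.2, 60, 0.5, 40)
        assert z1 == pytest.approx(-z2, rel=1e-14)

    def test_matches_direct_formula(self):
        z, p = fisher_z_compare(0.5, 103, 0.3, 103)
        expected_z = (np.arctanh(0.5) - np.arctanh(0.3)) / np.sqrt(2 / 100)
        assert z == pytest.approx(expected_z, rel=1e-12)
        assert p == pytest.approx(2 * scipy.stats.norm.sf(abs(expected_z)), rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.3, 50)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.3, 50)


class TestGasModelFit:
    T = np.linspace(0.0, 360.0, 181)
    P = (0.6, 0.3, 1 / 6, 120.0, 0.3, 1 / 6, 240.0)

    def test_noiseless_self_consistency(self):
        y = gas_model(self.T, *self.P)
        fit = fit_gas_model(y, self.T)
        assert fit.converged
        np.testing.assert_allclose(fit.params, self.P, rtol=1e-4)

    def test_constant_series_degenerate(self):
        fit = fit_gas_model(np.full(60, 2.5), np.linspace(0, 100, 60))
        assert fit.degenerate
        assert fit.baseline == pytest.approx(2.5)
        assert fit.rise_amplitude == 0.0 and fit.fall_amplitude == 0.0

    def test_shifted_switching_time_recovered_at_snr_10(self):
        rng = np.random.default_rng(17)
        shifted = (0.6, 0.3, 1 / 6, 150.0, 0.3, 1 / 6, 240.0)
        y = gas_model(self.T, *shifted)
        noise = 0.3 / 10.0  # amplitude / SNR
        dt = self.T[1] - self.T[0]
        errs = []
        for _ in range(5):
            fit = fit_gas_model(y + rng.normal(0, noise, y.size), self.T)
            errs.append(abs(fit.rise_time - 150.0))
        assert np.median(errs) <= 2.0  # within ~1 sample at dt = 2 s
        assert max(errs) <= 2 * dt

    def test_noncausal_flag(self):
        y = gas_model(self.T, *self.P)
        fit = fit_gas_model(y, self.T, stimulus_onsets=(125.0, 240.0))
        assert fit.noncausal
        fit_ok = fit_gas_model(y, self.T, stimulus_onsets=(120.0, 240.0))
        assert not fit_ok.noncausal

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_gas_model(np.ones(20), np.arange(20.0))
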