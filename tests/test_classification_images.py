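import numpy as np
import pytest

from ctdiscrim.gridspec import (
    FREQ_STEP,
    N_IMAGE,
    PIXEL_AREA_MM2,
    PIXEL_MM,
    ifft_centered,
    radial_freq_grid,
)
from ctdiscrim.classification_images import (
    FEATURE_FMAX,
    ClassificationImage,
    analytic_gradient_2d,
    classification_image_from_testing,
    classification_spectrum,
    differential_sampling_efficiency,
    fd_gradient_at,
    sampling_efficiency,
    score_weighted_field,
    smooth,
    spectral_features,
    unapodized_classification_image,
    _butterworth,
)
from ctdiscrim.observer_models import io_template, rescaled_template
from ctdiscrim.psychophysics import TrialRecord, run_testing_block
from conftest import make_io_observer

THETA = 0.7


class TestScoreWeightedField:
    def test_correct_trial_weight(self, cond_t3_a1):
        """A correct trial enters with weight (1-PC) * J/(J-1)."""
        diff = np.zeros((128, 128), dtype=np.float32)
        diff[64, 64] = 1.0
        tc = TrialRecord(0, outcome=1, theta=THETA, noise_diff=diff)
        tw = TrialRecord(0, outcome=0, theta=THETA, noise_diff=diff)
        pc, J = 0.8, 100
        fc = score_weighted_field(tc, pc, cond_t3_a1, J)
        fw = score_weighted_field(tw, pc, cond_t3_a1, J)
        assert fc.sum() != 0
        np.testing.assert_allclose(fc * (-pc / (1 - pc)), fw, rtol=1e-9)

    def test_missing_fields_rejected(self, cond_t3_a1):
        t = TrialRecord(0, outcome=1, theta=THETA)
        with pytest.raises(ValueError):
            score_weighted_field(t, 0.8, cond_t3_a1, 100)

    def test_accumulator_matches_per_trial_records(self, cond_t3_a1):
        """Streaming sums reproduce the record-based classification image."""
        obs = make_io_observer(cond_t3_a1, THETA, kappa=1.0)
        r1 = run_testing_block(
            obs, cond_t3_a1, THETA, np.random.default_rng(42), n_trials=40, collect="accumulate"
        )
        r2 = run_testing_block(
            obs, cond_t3_a1, THETA, np.random.default_rng(42), n_trials=40, collect="records"
        )
        for unapod in (False, True):
            a = classification_image_from_testing(r1, unapodized=unapod).image
            b = classification_image_from_testing(r2, unapodized=unapod).image
            # records store float32 noise fields, so agreement is single precision
            np.testing.assert_allclose(a, b, rtol=1e-3, atol=1e-4 * np.abs(a).max())

    def test_unapodized_equals_standard_for_a1(self, cond_t3_a1):
        obs = make_io_observer(cond_t3_a1, THETA, kappa=1.0)
        r = run_testing_block(
            obs, cond_t3_a1, THETA, np.random.default_rng(5), n_trials=30, collect="accumulate"
        )
        np.testing.assert_allclose(
            classification_image_from_testing(r).image,
            unapodized_classification_image(r).image,
            rtol=1e-10,
        )


class TestSmoothing:
    def test_spatial_window_half_max_radius(self):
        assert _butterworth(np.array(7.5), 7.5) == pytest.approx(0.5)
        assert _butterworth(np.array(0.0), 7.5) == pytest.approx(1.0)

    def test_symmetric_input_survives_symmetrization(self, cond_t3_a1):
        mu_t, mu_a = cond_t3_a1.mean_images(THETA)
        w = io_template(mu_t, mu_a, cond_t3_a1.noise, cond_t3_a1.apod, cond_t3_a1.display)
        ci = ClassificationImage(w.weights, cond_t3_a1)
        out = smooth(ci, radial=False).image
        # symmetric input: smoothing only applies the two windows
        assert np.abs(out).max() <= np.abs(w.weights).max() * (1 + 1e-9)
        np.testing.assert_allclose(out, np.roll(np.flip(out, 0), 1, axis=0), atol=1e-12)

    def test_smoothing_bounds_peak(self, cond_t3_a1, rng):
        ci = ClassificationImage(rng.standard_normal((128, 128)), cond_t3_a1)
        out = smooth(ci).image
        assert np.abs(out).max() <= np.abs(ci.image).max() * (1 + 1e-9)


class TestSpectraAndFeatures:
    def test_central_delta_flat_spectrum(self):
        img = np.zeros((128, 128))
        img[64, 64] = 1.0
        spec = classification_spectrum(img)
        np.testing.assert_allclose(spec.values, PIXEL_AREA_MM2, rtol=1e-9)

    def test_positive_blob_peaks_at_dc(self, cond_t3_a1):
        r = np.hypot(*np.meshgrid(*[np.arange(128) - 64] * 2, indexing="ij"))
        blob = np.exp(-((r / 6.0) ** 2))
        spec = classification_spectrum(blob)
        assert spec.values.argmax() == 0

    def test_io_template_spectrum_matches_closed_form(self, cond_t3_a1):
        c = cond_t3_a1
        mu_t, mu_a = c.mean_images(THETA)
        w = io_template(mu_t, mu_a, c.noise, c.apod, c.display)
        spec = classification_spectrum(w.weights)
        from ctdiscrim.gridspec import fft_centered

        closed = fft_centered(mu_t - mu_a).real / (
            c.sigma_hat() + c.display.quant_variance
        ) * PIXEL_AREA_MM2
        f = radial_freq_grid(N_IMAGE, PIXEL_MM)
        idx = np.rint(f / FREQ_STEP).astype(int).ravel()
        expect = np.bincount(idx, weights=closed.ravel()) / np.bincount(idx)
        np.testing.assert_allclose(spec.values, expect, rtol=1e-8, atol=1e-12)

    def test_feature_scaling_and_single_bin(self):
        img = np.zeros((128, 128))
        img[64, 64] = 1.0
        base = spectral_features(img)
        scaled = spectral_features(3.0 * img)
        assert scaled.integrated_power == pytest.approx(9 * base.integrated_power, rel=1e-9)
        assert scaled.mean_frequency == pytest.approx(base.mean_frequency, rel=1e-9)

    def test_features_blind_above_cutoff(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((128, 128))
        img = 0.5 * (img + np.roll(np.flip(img, 0), 1, 0))  # symmetrize
        f = radial_freq_grid(N_IMAGE, PIXEL_MM)
        delta = np.zeros((128, 128), dtype=complex)
        k, l = np.argwhere((f > FEATURE_FMAX + 3 * FREQ_STEP) & (f < FEATURE_FMAX + 4 * FREQ_STEP))[0]
        delta[k, l] = 50.0
        img2 = img + ifft_centered(delta).real
        a, b = spectral_features(img), spectral_features(img2)
        assert a.integrated_power == pytest.approx(b.integrated_power, rel=1e-6)
        assert a.mean_frequency == pytest.approx(b.mean_frequency, rel=1e-6)

    def test_lowpass_highpass_separated_by_mean_frequency(self):
        f = radial_freq_grid(N_IMAGE, PIXEL_MM)
        lo = np.where(f < 0.1, 1.0, 0.0)
        hi = np.where((f > 0.2) & (f < 0.3), 1.0, 0.0)
        img_lo = ifft_centered(lo).real
        img_hi = ifft_centered(hi).real
        a, b = spectral_features(img_lo), spectral_features(img_hi)
        assert b.mean_frequency > a.mean_frequency + 0.1


class TestSamplingEfficiency:
    def test_io_template_has_unit_sampling_efficiency(self, cond_t3_a1):
        mu_t, mu_a = cond_t3_a1.mean_images(THETA)
        w = io_template(mu_t, mu_a, cond_t3_a1.noise, cond_t3_a1.apod, cond_t3_a1.display)
        assert sampling_efficiency(w, cond_t3_a1, THETA) == pytest.approx(1.0, rel=1e-10)
        assert sampling_efficiency(5.0 * w.weights, cond_t3_a1, THETA) == pytest.approx(
            1.0, rel=1e-10
        )

    def test_gradient_zero_at_optimum(self, cond_t3_a1):
        mu_t, mu_a = cond_t3_a1.mean_images(THETA)
        w = io_template(mu_t, mu_a, cond_t3_a1.noise, cond_t3_a1.apod, cond_t3_a1.display)
        spec = differential_sampling_efficiency(w, cond_t3_a1, THETA)
        mistuned = rescaled_template(w, 0.8)
        ref = np.abs(
            differential_sampling_efficiency(mistuned, cond_t3_a1, THETA).values
        ).max()
        assert np.abs(spec.values).max() < 1e-8 * ref

    def test_finite_difference_matches_analytic(self, cond_t3_a1):
        mu_t, mu_a = cond_t3_a1.mean_images(THETA)
        w = io_template(mu_t, mu_a, cond_t3_a1.noise, cond_t3_a1.apod, cond_t3_a1.display)
        wm = rescaled_template(w, 0.8).weights
        g = analytic_gradient_2d(wm, cond_t3_a1, THETA)
        idx = [(0, 1), (3, 4), (0, 12)]
        fd = fd_gradient_at(wm, cond_t3_a1, THETA, idx)
        for (k, l), v in zip(idx, fd):
            assert v == pytest.approx(g[k, l], rel=1e-3)

    def test_oversized_epsilon_rejected(self, cond_t3_a1):
        mu_t, mu_a = cond_t3_a1.mean_images(THETA)
        w = io_template(mu_t, mu_a, cond_t3_a1.noise, cond_t3_a1.apod, cond_t3_a1.display)
        with pytest.raises(ValueError):
            fd_gradient_at(w.weights, cond_t3_a1, THETA, [(0, 1)], eps=1e12)

    def test_first_order_prediction(self, cond_t3_a1):
        """eta(w + sum eps_i d_i) ~ eta(w) + sum eps_i * grad_i for small eps."""
        from ctdiscrim.classification_images import choose_epsilon
        from ctdiscrim.gridspec import radius_grid

        c = cond_t3_a1
        mu_t, mu_a = c.mean_images(THETA)
        w = rescaled_template(
            io_template(mu_t, mu_a, c.noise, c.apod, c.display), 0.8
        ).weights
        g = analytic_gradient_2d(w, c, THETA)
        window = _butterworth(radius_grid(N_IMAGE, PIXEL_MM), 7.5)
        bins = [(0, 2), (4, 0), (2, 3)]
        pert = np.zeros_like(w)
        pred = 0.0
        for k, l in bins:
            delta = np.zeros((128, 128), dtype=complex)
            delta[k, l] = 1.0
            d = window * ifft_centered(delta).real / PIXEL_AREA_MM2
            eps = 0.002 * choose_epsilon(w, d)
            pert += eps * d
            pred += eps * g[k, l]
        base = sampling_efficiency(w, c, THETA)
        actual = sampling_efficiency(w + pert, c, THETA) - base
        assert actual == pytest.approx(pred, rel=5e-2)

    def test_undersized_template_underweights_low_frequencies(self, cond_t1_a1):
        """For a task with strong low-frequency signal, a shrunken template
        leaves the lowest bins underweighted (positive gradient)."""
        c = cond_t1_a1
        theta = 0.25
        mu_t, mu_a = c.mean_images(theta)
        w = io_template(mu_t, mu_a, c.noise, c.apod, c.display)
        spec = differential_sampling_efficiency(rescaled_template(w, 0.7), c, theta)
        assert (spec.values[:3] > 0).all()
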