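import numpy as np
import pytest

from ctdiscrim.gridspec import FREQ_STEP, N_FINE, PIXEL_MM, radius_grid
from ctdiscrim.imaging_chain import (
    APOD_LEVELS,
    SYSTEM1,
    SYSTEM2,
    ApodizationSpec,
    Condition,
    DisplayModel,
    NoiseModel,
    SystemSpec,
    apod_value,
    apply_transfer_and_downsample,
    calibrate_noise_scale,
    discrete_spectrum,
    mtf_value,
    nps_value,
    pixel_sd_analytic,
    render_stimulus,
    resolution_10pct,
    sample_noise_pair,
)
from ctdiscrim.phantom_tasks import TaskSpec, make_benign_object

A1 = ApodizationSpec("A1", None)


class TestTransferFunctions:
    @pytest.mark.parametrize("sys", [SYSTEM1, SYSTEM2])
    def test_mtf_anchor_points(self, sys):
        assert mtf_value(0.0, sys) == pytest.approx(1.0)
        assert mtf_value(sys.f0 / 2, sys) == pytest.approx(0.5)
        assert mtf_value(sys.f0, sys) == pytest.approx(0.0, abs=1e-12)
        assert mtf_value(2 * sys.f0, sys) == 0.0

    def test_apod_anchor_points(self):
        ap = ApodizationSpec("A3", 0.59)
        assert apod_value(0.0, ap) == pytest.approx(1.0)
        assert apod_value(ap.fc, ap) == pytest.approx(0.0, abs=1e-12)
        assert apod_value(ap.fc / 2, ap) == pytest.approx(2 / np.pi)
        assert apod_value(10.0, A1) == 1.0

    @pytest.mark.parametrize("sys", [SYSTEM1, SYSTEM2])
    def test_resolution_decreases_with_apodization(self, sys):
        res = [
            resolution_10pct(sys, ApodizationSpec.for_level(lvl, sys)) for lvl in APOD_LEVELS
        ]
        assert all(a > b for a, b in zip(res, res[1:]))


class TestNoiseModel:
    def test_nps_branches_continuous_at_knee(self):
        nm = NoiseModel(c_n=100.0)
        eps = 1e-9
        assert nps_value(nm.f_l - eps, nm) == pytest.approx(nps_value(nm.f_l + eps, nm), rel=1e-6)
        assert nps_value(nm.f_l, nm) == pytest.approx(nm.c_n * nm.f_l)

    def test_nps_ramp_and_cutoff(self):
        nm = NoiseModel(c_n=50.0)
        assert nps_value(nm.f_nyq, nm) / nps_value(nm.f_nyq / 2, nm) == pytest.approx(2.0)
        assert nps_value(2 * nm.f_nyq, nm) == 0.0

    def test_calibration_fixed_point_and_scaling(self):
        nm = calibrate_noise_scale(NoiseModel(), 166.5)
        assert nm.c_n > 0
        assert pixel_sd_analytic(nm, A1) == pytest.approx(166.5, rel=1e-12)
        nm2 = calibrate_noise_scale(NoiseModel(), 333.0)
        assert nm2.c_n == pytest.approx(4 * nm.c_n, rel=1e-9)

    @pytest.mark.parametrize("sys", [SYSTEM1, SYSTEM2])
    def test_pixel_sd_strictly_decreases_with_apodization(self, sys):
        nm = calibrate_noise_scale(NoiseModel())
        sds = [
            pixel_sd_analytic(nm, ApodizationSpec.for_level(lvl, sys)) for lvl in APOD_LEVELS
        ]
        assert all(a > b for a, b in zip(sds, sds[1:]))


class TestNoiseSynthesis:
    def test_unapodized_member_independent_of_apod_level(self):
        nm = calibrate_noise_scale(NoiseModel())
        a2 = ApodizationSpec.for_level("A2", SYSTEM1)
        a4 = ApodizationSpec.for_level("A4", SYSTEM1)
        _, un1 = sample_noise_pair(nm, a2, np.random.default_rng(5))
        _, un2 = sample_noise_pair(nm, a4, np.random.default_rng(5))
        np.testing.assert_array_equal(un1, un2)

    def test_empirical_sd_matches_analytic(self):
        nm = calibrate_noise_scale(NoiseModel())
        a3 = ApodizationSpec.for_level("A3", SYSTEM2)
        rng = np.random.default_rng(6)
        draws = [sample_noise_pair(nm, a3, rng) for _ in range(200)]
        sd_ap = np.std([d[0] for d in draws])
        sd_un = np.std([d[1] for d in draws])
        assert sd_ap == pytest.approx(pixel_sd_analytic(nm, a3), rel=0.03)
        assert sd_un == pytest.approx(166.5, rel=0.03)

    def test_mean_periodogram_matches_discrete_spectrum(self):
        """Monte-Carlo periodogram converges to the synthesis NPS bin-wise."""
        nm = calibrate_noise_scale(NoiseModel())
        a2 = ApodizationSpec.for_level("A2", SYSTEM1)
        rng = np.random.default_rng(7)
        acc = np.zeros((128, 128))
        n_draws = 200
        for _ in range(n_draws):
            f, _ = sample_noise_pair(nm, a2, rng)
            acc += np.abs(np.fft.fft2(f)) ** 2
        # periodogram in spectrum units: |fft|^2 * dpix^2 / Npix
        period = acc / n_draws * PIXEL_MM**2 / 128**2
        target = discrete_spectrum(nm, a2)
        mask = target > 0.05 * target.max()
        rel = (period[mask] - target[mask]) / target[mask]
        # chi2 sampling error ~ 1/sqrt(200) = 7% per bin
        assert np.abs(rel.mean()) < 0.02
        assert np.abs(rel).max() < 5 / np.sqrt(n_draws)


class TestTransferAndDownsample:
    def test_uniform_object_preserves_background(self):
        from ctdiscrim.gridspec import FINE_PITCH_MM
        from ctdiscrim.phantom_tasks import FineGrid

        obj = FineGrid(np.full((N_FINE, N_FINE), -1000.0), FINE_PITCH_MM)
        mu = apply_transfer_and_downsample(obj, SYSTEM1, ApodizationSpec.for_level("A3", SYSTEM1))
        np.testing.assert_allclose(mu, -1000.0, atol=1e-8)

    def test_allpass_chain_reproduces_profile_at_pixel_centers(self):
        spec = TaskSpec("T3", 0.0)
        obj = make_benign_object(spec)
        wide_open = SystemSpec(1e6)  # MTF ~ 1 over the fine band
        mu = apply_transfer_and_downsample(obj, wide_open, A1)
        np.testing.assert_allclose(mu, obj.values[::9, ::9], atol=1e-6)

    def test_filtering_reduces_difference_energy(self):
        from ctdiscrim.phantom_tasks import difference_object

        d = difference_object(TaskSpec("T1", 0.3))
        full = (d.values[::9, ::9] ** 2).sum()
        filt = (
            apply_transfer_and_downsample(d, SYSTEM1, ApodizationSpec.for_level("A3", SYSTEM1))
            ** 2
        ).sum()
        assert filt < full


class TestDisplayAndStimulus:
    def test_display_quantization_model(self):
        dm = DisplayModel()
        assert dm.quant_step == pytest.approx(1500 / 256)
        assert dm.quant_variance == pytest.approx(dm.quant_step**2 / 12)
        img = np.array([[-1400.0, -650.0, 101.0, -2000.0]])
        out = dm.render(img)
        assert out[0, 0] == 0  # window floor
        assert out[0, 1] == 128  # level maps to mid-gray
        assert out[0, 2] == 255  # above window ceiling truncates
        assert out[0, 3] == 0

    def test_stimulus_decomposition_exact(self, cond_t3_a2, rng):
        pair = render_stimulus(cond_t3_a2, 0.5, rng)
        np.testing.assert_array_equal(pair.target, pair.mu_target + pair.noise_target)
        np.testing.assert_array_equal(
            pair.alternative, pair.mu_alternative + pair.noise_alternative
        )

    def test_t3_mean_linearity_matches_direct_render(self, cond_t3_a2):
        from ctdiscrim.phantom_tasks import make_malignant_object

        mu_t, _ = cond_t3_a2.mean_images(0.33)
        direct = apply_transfer_and_downsample(
            make_malignant_object(TaskSpec("T3", 0.33)), cond_t3_a2.system, cond_t3_a2.apod
        )
        np.testing.assert_allclose(mu_t, direct, atol=1e-9)
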