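"""Linear observers: the Ideal Observer and synthetic stand-ins for subjects.

For equal-covariance Gaussian classes the optimal classifier is a linear
template — the prewhitened matched filter — with frequency weights
``w_IO = (mu_T_hat - mu_A_hat) / (Sigma_hat + sigma_Q^2)``, where
``Sigma_hat`` is the discrete noise power spectrum of the condition and
``sigma_Q^2`` the quantization-noise variance that regularizes frequencies
nulled by apodization.

Synthetic observers are linear templates plus additive Gaussian internal
noise on the decision variable, expressed in units of the template-response
standard deviation.  An observer with internal-noise multiplier ``kappa`` has
``SNR_eff = SNR / sqrt(1 + kappa^2)`` and hence efficiency
``1 / (1 + kappa^2)`` when using the Ideal Observer's template, so target
efficiencies can be dialed in a priori.  Mis-tuned templates (spatially
rescaled, or with attenuated low frequencies) provide stand-ins for the
sub-optimal weighting patterns real readers exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .gridspec import FREQ_STEP, N_IMAGE, PIXEL_AREA_MM2, fft_centered, ifft_centered
from .imaging_chain import ApodizationSpec, Condition, DisplayModel, NoiseModel, StimulusPair
from .imaging_chain import discrete_spectrum as _discrete_spectrum

__all__ = [
    "Template",
    "ObserverSpec",
    "io_template",
    "template_snr",
    "response_sd",
    "decide_2afc",
    "effective_snr",
    "rescaled_template",
    "lowfreq_attenuated_template",
]


@dataclass(frozen=True)
class Template:
    """A 128x128 spatial weighting pattern (HU^-1), centered on the lesion."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_IMAGE, N_IMAGE):
            raise ValueError(f"template must be {N_IMAGE}x{N_IMAGE}")
        object.__setattr__(self, "weights", w)

    @property
    def freq_form(self) -> np.ndarray:
        """FT of the centered weights times the pixel area (HU^-1 mm^2)."""
        return fft_centered(self.weights) * PIXEL_AREA_MM2


@dataclass(frozen=True)
class ObserverSpec:
    """A linear template plus internal decision noise (in response-SD units)."""

    template: Template
    internal_noise_sd: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be non-negative")


def _denominator(noise: NoiseModel, apod: ApodizationSpec, display: DisplayModel) -> np.ndarray:
    return _discrete_spectrum(noise, apod) + display.quant_variance


def io_template(
    mu_target: np.ndarray,
    mu_alternative: np.ndarray,
    noise: NoiseModel,
    apod: ApodizationSpec,
    display: DisplayModel,
) -> Template:
    """Prewhitened matched filter for the condition's signal and noise."""
    dmu_hat = fft_centered(mu_target - mu_alternative)
    w_hat = dmu_hat / _denominator(noise, apod, display)
    return Template(ifft_centered(w_hat).real)


def template_snr(
    template: Template,
    mu_target: np.ndarray,
    mu_alternative: np.ndarray,
    noise: NoiseModel,
    apod: ApodizationSpec,
    display: DisplayModel,
) -> float:
    """SNR of a linear template: mean response difference over response SD.

    The response variance is evaluated in the frequency domain as
    ``df^2 * sum((Sigma_hat + sigma_Q^2) |w_hat|^2)``, the discrete quadrature
    of the covariance quadratic form; with the noise normalization used by
    the imaging chain this is the exact variance of ``sum(w * g)`` under the
    external noise (plus the small quantization regularizer).
    """
    w = template.weights
    drho = float((w * (mu_target - mu_alternative)).sum())
    sd = response_sd(template, noise, apod, display)
    if sd == 0:
        raise ValueError("template has zero response variance")
    return drho / sd


def response_sd(
    template: Template,
    noise: NoiseModel,
    apod: ApodizationSpec,
    display: DisplayModel,
) -> float:
    """Standard deviation of the template response to one stimulus."""
    w_hat = fft_centered(template.weights)
    var = FREQ_STEP**2 * float(
        (_denominator(noise, apod, display) * np.abs(w_hat) ** 2).sum()
    )
    return float(np.sqrt(var))


def decide_2afc(
    obs: ObserverSpec,
    pair: StimulusPair,
    rng: np.random.Generator,
    resp_sd: float | None = None,
    internal_draws: tuple[float, float] | None = None,
) -> int:
    """One 2AFC decision: 1 if the target stimulus wins, else 0.

    Internal noise draws are attached positionally to (target, alternative);
    passing ``internal_draws`` explicitly makes the decision deterministic
    (swapping the stimuli together with their draws flips the outcome).
    Exact ties are broken by a fair coin.
    """
    w = obs.template.weights
    r_t = float((w * pair.target).sum())
    r_a = float((w * pair.alternative).sum())
    if obs.internal_noise_sd > 0:
        if resp_sd is None:
            c = pair.condition
            resp_sd = response_sd(obs.template, c.noise, c.apod, c.display)
        if internal_draws is None:
            internal_draws = tuple(rng.standard_normal(2))
        r_t += obs.internal_noise_sd * resp_sd * internal_draws[0]
        r_a += obs.internal_noise_sd * resp_sd * internal_draws[1]
    if r_t > r_a:
        return 1
    if r_t < r_a:
        return 0
    return int(rng.integers(2))


def effective_snr(obs: ObserverSpec, condition: Condition, theta: float) -> float:
    """Template SNR attenuated by internal noise: SNR / sqrt(1 + kappa^2)."""
    mu_t, mu_a = condition.mean_images(theta)
    snr = template_snr(obs.template, mu_t, mu_a, condition.noise, condition.apod, condition.display)
    return snr / float(np.sqrt(1.0 + obs.internal_noise_sd**2))


def rescaled_template(template: Template, scale: float) -> Template:
    """Radially rescale the spatial weights about the center.

    ``scale < 1`` shrinks the template (samples the original at larger
    radii), emulating a reader using an undersized perceived lesion size.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = N_IMAGE // 2
    idx = np.arange(N_IMAGE, dtype=float)
    coords = np.meshgrid((idx - c) / scale + c, (idx - c) / scale + c, indexing="ij")
    out = map_coordinates(template.weights, coords, order=1, mode="constant", cval=0.0)
    return Template(out)


def lowfreq_attenuated_template(template: Template, f_knee: float, order: int = 2) -> Template:
    """Attenuate frequencies below ``f_knee`` (cyc/mm) by a Butterworth-style
    high-pass ``(f/f_knee)^(2p) / (1 + (f/f_knee)^(2p))``; the result is
    symmetrized so the weights stay real."""
    from .gridspec import PIXEL_MM, radial_freq_grid

    f = radial_freq_grid(N_IMAGE, PIXEL_MM)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (f / f_knee) ** (2 * order)
    hp = np.where(np.isfinite(x), x / (1.0 + x), 1.0)
    hp[f == 0] = 0.0
    w_hat = fft_centered(template.weights) * hp
    return Template(ifft_centered(w_hat).real)
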