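"""Simulated imaging systems: MTF, apodization, ramp-spectrum noise, display.

Two systems are modeled, differing only in resolution.  Each has a
cosine-rolloff MTF, ``M(f) = 1/2 + 1/2 cos(pi f / f0)`` for ``f <= f0``,
with cutoff ``f0 = 0.59`` cyc/mm (System 1) or ``0.73`` cyc/mm (System 2, the
Nyquist frequency of the 0.684 mm pixel grid).  Reconstruction-style noise
control is applied by Shepp-Logan (Sinc-profile) apodization filters at four
levels: none (A1), first zero at ``2 f0`` (A2), at ``f0`` (A3) and at
``0.8 f0`` (A4).

Image noise is a stationary Gaussian process with a ramp power spectrum
``N(f) = C_N f`` out to the pixel Nyquist frequency, leveling quadratically
below 5% of Nyquist, and attenuated by the apodization filter squared.  The
ramp scale ``C_N`` is calibrated so the unapodized pixel standard deviation
matches a target value (166.5 HU by default).

Noise fields are synthesized directly on the 128x128 image grid by filtering
Gaussian white noise in the frequency domain.  Each draw is filtered twice —
with the condition's apodization and with none — so that every trial retains
a matched "unapodized" noise field for classification-image analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .gridspec import (
    F_NYQUIST,
    FINE_PITCH_MM,
    FREQ_STEP,
    N_IMAGE,
    PIXEL_MM,
    radial_freq_grid,
)
from .phantom_tasks import (
    FineGrid,
    TaskSpec,
    difference_object,
    make_benign_object,
    make_malignant_object,
)

__all__ = [
    "SystemSpec",
    "ApodizationSpec",
    "NoiseModel",
    "DisplayModel",
    "StimulusPair",
    "Condition",
    "SYSTEM1",
    "SYSTEM2",
    "APOD_LEVELS",
    "mtf_value",
    "apod_value",
    "resolution_10pct",
    "nps_value",
    "calibrate_noise_scale",
    "pixel_sd_analytic",
    "apply_transfer_and_downsample",
    "sample_noise_pair",
    "render_stimulus",
]


@dataclass(frozen=True)
class SystemSpec:
    """An imaging system, characterized by its cosine-rolloff MTF cutoff."""

    f0: float
    name: str = ""

    def __post_init__(self):
        if self.f0 <= 0:
            raise ValueError("MTF cutoff f0 must be positive")


SYSTEM1 = SystemSpec(0.59, "S1")
SYSTEM2 = SystemSpec(0.73, "S2")

#: apodization cutoff as a multiple of the system MTF cutoff; None = no filter
APOD_LEVELS = {"A1": None, "A2": 2.0, "A3": 1.0, "A4": 0.8}


@dataclass(frozen=True)
class ApodizationSpec:
    """A Shepp-Logan apodization level; ``fc=None`` means no apodization."""

    level: str
    fc: float | None

    @classmethod
    def for_level(cls, level: str, system: SystemSpec) -> "ApodizationSpec":
        if level not in APOD_LEVELS:
            raise ValueError(f"unknown apodization level {level!r}")
        factor = APOD_LEVELS[level]
        return cls(level, None if factor is None else factor * system.f0)


def mtf_value(f, sys: SystemSpec):
    """Cosine-rolloff MTF, 1 at DC, 0 at and beyond ``f0``."""
    f = np.asarray(f, dtype=float)
    out = np.where(f <= sys.f0, 0.5 + 0.5 * np.cos(np.pi * np.minimum(f, sys.f0) / sys.f0), 0.0)
    return out if out.ndim else float(out)


def apod_value(f, apod: ApodizationSpec):
    """Shepp-Logan (Sinc) apodization: sin(pi f/fc)/(pi f/fc) up to ``fc``."""
    f = np.asarray(f, dtype=float)
    if apod.fc is None:
        out = np.ones_like(f)
    else:
        x = f / apod.fc
        out = np.where(x <= 1.0, np.sinc(x), 0.0)
    return out if out.ndim else float(out)


def resolution_10pct(sys: SystemSpec, apod: ApodizationSpec) -> float:
    """Frequency (cyc/mm) where the combined M(f)A(f) falls to 10% of max."""

    def g(f):
        return float(mtf_value(f, sys) * apod_value(f, apod)) - 0.1

    return brentq(g, 1e-9, sys.f0)


@dataclass(frozen=True)
class NoiseModel:
    """Ramp NPS with quadratic low-frequency leveling and radial Nyquist cutoff.

    ``N(f) = (C_N/2)(f^2/f_L + f_L)`` for ``f <= f_L``, ``C_N f`` for
    ``f_L < f <= f_Nyq`` and zero beyond; the two branches agree at ``f_L``.
    Units: HU^2 mm^2 on the discrete grid after multiplying by nothing — the
    discrete spectrum is just N sampled at the grid frequencies, times the
    apodization squared.
    """

    c_n: float = 1.0
    f_nyq: float = F_NYQUIST
    f_l: float = 0.05 * F_NYQUIST

    def __post_init__(self):
        if self.c_n <= 0 or self.f_l <= 0 or self.f_nyq <= self.f_l:
            raise ValueError("invalid noise model parameters")


def nps_value(f, noise: NoiseModel):
    """Radial noise power spectrum, HU^2 mm^2."""
    f = np.asarray(f, dtype=float)
    level = 0.5 * noise.c_n * (f**2 / noise.f_l + noise.f_l)
    ramp = noise.c_n * f
    out = np.where(f <= noise.f_l, level, ramp)
    out = np.where(f <= noise.f_nyq, out, 0.0)
    return out if out.ndim else float(out)


@lru_cache(maxsize=64)
def _discrete_spectrum_cached(c_n: float, f_nyq: float, f_l: float, fc) -> np.ndarray:
    noise = NoiseModel(c_n, f_nyq, f_l)
    apod = ApodizationSpec("_", fc)
    f = radial_freq_grid(N_IMAGE, PIXEL_MM)
    spec = nps_value(f, noise) * apod_value(f, apod) ** 2
    spec.flags.writeable = False
    return spec


def discrete_spectrum(noise: NoiseModel, apod: ApodizationSpec) -> np.ndarray:
    """128x128 discrete NPS (unshifted FFT ordering), HU^2 mm^2."""
    return _discrete_spectrum_cached(noise.c_n, noise.f_nyq, noise.f_l, apod.fc)


def pixel_sd_analytic(noise: NoiseModel, apod: ApodizationSpec) -> float:
    """Pixel standard deviation implied by the discrete NPS, HU.

    Variance is the frequency-bin area times the sum of the discrete spectrum,
    ``var = df^2 * sum(N * A^2)``.
    """
    return float(math.sqrt(FREQ_STEP**2 * discrete_spectrum(noise, apod).sum()))


def calibrate_noise_scale(noise: NoiseModel, target_sd: float = 166.5) -> NoiseModel:
    """Scale ``C_N`` so the unapodized analytic pixel SD equals ``target_sd``."""
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    no_apod = ApodizationSpec("A1", None)
    sd_unit = pixel_sd_analytic(replace(noise, c_n=1.0), no_apod)
    return replace(noise, c_n=(target_sd / sd_unit) ** 2)


@dataclass(frozen=True)
class DisplayModel:
    """Lung window/level display with 8-bit quantization."""

    window: float = 1500.0
    level: float = -650.0
    bits: int = 8

    @property
    def quant_step(self) -> float:
        return self.window / 2**self.bits

    @property
    def quant_variance(self) -> float:
        # uniform-quantization noise variance, (step^2)/12
        return self.quant_step**2 / 12.0

    def render(self, image: np.ndarray) -> np.ndarray:
        """Window, truncate and discretize to 8-bit gray for viewing exports."""
        lo = self.level - self.window / 2.0
        levels = 2**self.bits
        bins = np.floor((image - lo) / self.quant_step)
        return np.clip(bins, 0, levels - 1).astype(np.uint8)


@lru_cache(maxsize=16)
def _fine_transfer(f0: float, fc) -> np.ndarray:
    sys = SystemSpec(f0)
    apod = ApodizationSpec("_", fc)
    f = radial_freq_grid(N_IMAGE * 9, FINE_PITCH_MM)
    h = mtf_value(f, sys) * apod_value(f, apod)
    h.flags.writeable = False
    return h


def apply_transfer_and_downsample(
    obj: FineGrid, sys: SystemSpec, apod: ApodizationSpec
) -> np.ndarray:
    """Filter a fine-grid object by M*A and decimate 9x to the image grid.

    The lesion center (fine index 576) lands exactly on the coarse center
    (index 64); the DC gain of the chain is 1 so the background is preserved.
    """
    n = obj.values.shape[0]
    if n != N_IMAGE * 9:
        raise ValueError(f"expected a {N_IMAGE * 9} fine grid, got {n}")
    spec = np.fft.fft2(obj.values) * _fine_transfer(sys.f0, apod.fc)
    filtered = np.fft.ifft2(spec).real
    return np.ascontiguousarray(filtered[::9, ::9])


def sample_noise_pair(
    noise: NoiseModel, apod: ApodizationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One white-noise draw filtered two ways: (apodized, unapodized).

    Both fields share the same underlying white-noise realization, so the
    apodized field is the unapodized one passed through the apodization
    filter.  Normalization is fixed so that the pixel variance equals
    ``df^2 * sum(spectrum)``, matching :func:`pixel_sd_analytic`.
    """
    z = rng.standard_normal((N_IMAGE, N_IMAGE))
    zhat = np.fft.fft2(z)
    base = np.sqrt(discrete_spectrum(noise, ApodizationSpec("A1", None)))
    apodized = np.sqrt(discrete_spectrum(noise, apod))
    n_unapod = np.fft.ifft2(zhat * base).real / PIXEL_MM
    n_apod = np.fft.ifft2(zhat * apodized).real / PIXEL_MM
    return n_apod, n_unapod


@dataclass(frozen=True)
class StimulusPair:
    """One 2AFC trial: target (malignant) and alternative (benign) stimuli.

    ``target = mu_target + noise_target`` exactly; the matched unapodized
    noise fields come from the same white-noise draws as the apodized ones.
    """

    target: np.ndarray
    alternative: np.ndarray
    mu_target: np.ndarray
    mu_alternative: np.ndarray
    noise_target: np.ndarray
    noise_alternative: np.ndarray
    noise_target_unapod: np.ndarray
    noise_alternative_unapod: np.ndarray
    condition: "Condition"
    theta: float
    seed: object = None


@dataclass
class Condition:
    """One experimental condition: task x system x apodization (+ noise, display)."""

    task_id: str
    system: SystemSpec
    apod: ApodizationSpec
    noise: NoiseModel
    display: DisplayModel = field(default_factory=DisplayModel)
    _mean_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def create(
        cls,
        task_id: str,
        system: SystemSpec,
        apod_level: str,
        target_sd: float = 166.5,
        display: DisplayModel | None = None,
    ) -> "Condition":
        apod = ApodizationSpec.for_level(apod_level, system)
        noise = calibrate_noise_scale(NoiseModel(), target_sd)
        return cls(task_id, system, apod, noise, display or DisplayModel())

    @property
    def label(self) -> str:
        return f"{self.task_id}-{self.system.name}-{self.apod.level}"

    def task_spec(self, theta: float) -> TaskSpec:
        return TaskSpec(self.task_id, theta)

    def _mu_alternative(self) -> np.ndarray:
        # the benign mean image does not depend on theta
        if "mu_alt" not in self._mean_cache:
            spec = self.task_spec(0.0)
            self._mean_cache["mu_alt"] = apply_transfer_and_downsample(
                make_benign_object(spec), self.system, self.apod
            )
        return self._mean_cache["mu_alt"]

    def mean_images(self, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """(mu_target, mu_alternative) on the image grid; cached per theta.

        For T3 the malignant mean is linear in theta, so only a unit
        difference response is ever rendered; T1/T2 rebuild the fine object
        per distinct theta.
        """
        key = float(theta)
        mu_a = self._mu_alternative()
        if key not in self._mean_cache:
            if self.task_id == "T3":
                if "t3_unit" not in self._mean_cache:
                    unit = difference_object(self.task_spec(1.0))
                    self._mean_cache["t3_unit"] = apply_transfer_and_downsample(
                        unit, self.system, self.apod
                    )
                mu_t = mu_a + key * self._mean_cache["t3_unit"]
            else:
                mu_t = apply_transfer_and_downsample(
                    make_malignant_object(self.task_spec(theta)), self.system, self.apod
                )
            self._mean_cache[key] = mu_t
        return self._mean_cache[key], mu_a

    def sigma_hat(self) -> np.ndarray:
        """Discrete NPS of the condition's (apodized) noise, HU^2 mm^2."""
        return discrete_spectrum(self.noise, self.apod)

    def sigma_hat_unapod(self) -> np.ndarray:
        """Discrete NPS of the matched unapodized noise."""
        return discrete_spectrum(self.noise, ApodizationSpec("A1", None))

    def render_trial(self, theta: float, rng: np.random.Generator, seed=None) -> StimulusPair:
        return render_stimulus(self, theta, rng, seed=seed)


def render_stimulus(
    condition: Condition, theta: float, rng: np.random.Generator, seed=None
) -> StimulusPair:
    """Draw one 2AFC stimulus pair with independent noise per alternative.

    Analysis operates on the unquantized HU images; window/level/8-bit
    rendering (``DisplayModel.render``) is applied only for viewing exports.
    """
    mu_t, mu_a = condition.mean_images(theta)
    n_t, n_t_un = sample_noise_pair(condition.noise, condition.apod, rng)
    n_a, n_a_un = sample_noise_pair(condition.noise, condition.apod, rng)
    return StimulusPair(
        target=mu_t + n_t,
        alternative=mu_a + n_a,
        mu_target=mu_t,
        mu_alternative=mu_a,
        noise_target=n_t,
        noise_alternative=n_a,
        noise_target_unapod=n_t_un,
        noise_alternative_unapod=n_a_un,
        condition=condition,
        theta=float(theta),
        seed=seed,
    )
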