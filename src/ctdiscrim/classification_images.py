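"""Classification images from 2AFC trial logs, and their spectral analysis.

A linear observer's spatial weights can be recovered from forced-choice data
by reverse correlation: each trial contributes a score-weighted, prewhitened
noise-field difference

    dq_hat = (O - PC) * (J/(J-1)) * (n+_hat - n-_hat) / (Sigma_hat + sigma_Q^2),

whose average over trials (and readers) is proportional to the template used
to perform the task.  The raw estimate is noisy — particularly under strong
apodization, where the denominator is small — so estimates are smoothed by a
4th-order Butterworth spatial window (half-max radius 7.5 mm), a 4th-order
Butterworth frequency window (radius 0.4 cyc/mm, with the imaginary part of
the spectrum zeroed to enforce symmetry), and averaging over one-pixel-wide
radial annuli.

From the smoothed estimate we compute radial spectra, two spectral features
(integrated power and mean frequency below 0.35 cyc/mm), sampling efficiency
against the Ideal Observer, its per-frequency gradient ("differential
sampling efficiency"), and the "unapodized" variant in which the matched
pre-apodization noise fields and the unapodized NPS are used, treating
apodization as part of the observer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gridspec import (
    FREQ_STEP,
    N_IMAGE,
    PIXEL_AREA_MM2,
    PIXEL_MM,
    fft_centered,
    ifft_centered,
    radial_freq_grid,
    radius_grid,
)
from .imaging_chain import ApodizationSpec, Condition
from .imaging_chain import discrete_spectrum as _discrete_spectrum
from .observer_models import Template, io_template, template_snr
from .psychophysics import TestingResult, TrialRecord

__all__ = [
    "ClassificationImage",
    "RadialSpectrum",
    "SpectralFeatures",
    "score_weighted_field",
    "average_classification_image",
    "classification_image_from_testing",
    "unapodized_classification_image",
    "smooth",
    "classification_spectrum",
    "spectral_features",
    "sampling_efficiency",
    "differential_sampling_efficiency",
    "FEATURE_FMAX",
]

#: spectral-feature integration cutoff, cyc/mm (strict inequality)
FEATURE_FMAX = 0.35
SPATIAL_HWHM_MM = 7.5
FREQ_RADIUS_CYC_MM = 0.4


@dataclass(frozen=True)
class ClassificationImage:
    """An estimated 128x128 spatial weighting pattern (HU^-1)."""

    image: np.ndarray
    condition: Condition | None = None
    unapodized: bool = False
    smoothed: bool = False
    n_trials: int = 0
    n_subjects: int = 1

    def as_template(self) -> Template:
        return Template(self.image)


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially bin-averaged frequency profile; bin width = one freq sample."""

    freq: np.ndarray
    values: np.ndarray
    bin_width: float = FREQ_STEP


@dataclass(frozen=True)
class SpectralFeatures:
    """Integrated power (HU^-2 mm^2) and mean frequency (cyc/mm) below fmax."""

    integrated_power: float
    mean_frequency: float
    fmax: float = FEATURE_FMAX


def _butterworth(x: np.ndarray, half_max: float, order: int = 4) -> np.ndarray:
    return 1.0 / (1.0 + (x / half_max) ** (2 * order))


def _denominator(condition: Condition, unapodized: bool) -> np.ndarray:
    if unapodized:
        sigma = _discrete_spectrum(condition.noise, ApodizationSpec("A1", None))
    else:
        sigma = condition.sigma_hat()
    return sigma + condition.display.quant_variance


def score_weighted_field(
    trial: TrialRecord,
    pc: float,
    condition: Condition,
    n_trials: int,
    unapodized: bool = False,
) -> np.ndarray:
    """Spatial score-weighted prewhitened noise-field difference for one trial."""
    diff = trial.noise_diff_unapod if unapodized else trial.noise_diff
    if diff is None:
        raise ValueError("trial record does not carry the required noise fields")
    if n_trials < 2:
        raise ValueError("need at least two trials for the sample-PC correction")
    dhat = np.fft.fft2(diff.astype(float)) / _denominator(condition, unapodized)
    scale = (trial.outcome - pc) * n_trials / (n_trials - 1.0)
    return np.fft.ifft2(scale * dhat).real


def average_classification_image(
    records: list[TrialRecord],
    condition: Condition,
    pc: float | None = None,
    unapodized: bool = False,
) -> ClassificationImage:
    """Grand-mean classification image over a list of trial records."""
    if not records:
        raise ValueError("no trial records")
    if pc is None:
        pc = float(np.mean([t.outcome for t in records]))
    acc = np.zeros((N_IMAGE, N_IMAGE))
    for t in records:
        acc += score_weighted_field(t, pc, condition, len(records), unapodized)
    return ClassificationImage(
        acc / len(records), condition=condition, unapodized=unapodized, n_trials=len(records)
    )


def _image_from_sums(
    sum_scored: np.ndarray,
    sum_field: np.ndarray,
    n: int,
    pc: float,
    condition: Condition,
    unapodized: bool,
) -> ClassificationImage:
    # sum over trials of (O_j - PC) F_j = sum(O_j F_j) - PC * sum(F_j)
    num = (sum_scored - pc * sum_field) * (n / (n - 1.0)) / n
    w_hat = num / _denominator(condition, unapodized)
    return ClassificationImage(
        np.fft.ifft2(w_hat).real,
        condition=condition,
        unapodized=unapodized,
        n_trials=n,
    )


def classification_image_from_testing(
    testing: TestingResult, unapodized: bool = False
) -> ClassificationImage:
    """Classification image for one observer's testing block.

    Works from either the streaming accumulator or stored trial records,
    whichever the block retained.
    """
    cond = testing.condition
    if cond is None:
        raise ValueError("testing result carries no condition")
    if testing.accumulator is not None:
        a = testing.accumulator
        if unapodized:
            return _image_from_sums(
                a.sum_scored_unapod, a.sum_field_unapod, a.n, testing.pc, cond, True
            )
        return _image_from_sums(a.sum_scored, a.sum_field, a.n, testing.pc, cond, False)
    if testing.records is not None:
        return average_classification_image(testing.records, cond, testing.pc, unapodized)
    raise ValueError("testing block retained neither accumulator nor records")


def unapodized_classification_image(testing: TestingResult) -> ClassificationImage:
    """Classification image built from the matched pre-apodization noise
    fields and the unapodized NPS, with the responses unchanged."""
    return classification_image_from_testing(testing, unapodized=True)


def pool_classification_images(images: list[ClassificationImage]) -> ClassificationImage:
    """Average classification images across subjects (equal weights)."""
    if not images:
        raise ValueError("no images to pool")
    stack = np.mean([ci.image for ci in images], axis=0)
    first = images[0]
    return replace(first, image=stack, n_subjects=len(images))


def _radial_band_average(img: np.ndarray) -> np.ndarray:
    """Average over one-pixel-wide annuli about the center."""
    r = radius_grid(N_IMAGE, PIXEL_MM)
    idx = np.rint(r / PIXEL_MM).astype(int).ravel()
    sums = np.bincount(idx, weights=img.ravel())
    counts = np.bincount(idx)
    means = sums / counts
    return means[idx].reshape(img.shape)


def smooth(
    ci: ClassificationImage,
    spatial_hwhm: float = SPATIAL_HWHM_MM,
    freq_radius: float = FREQ_RADIUS_CYC_MM,
    radial: bool = True,
) -> ClassificationImage:
    """Standard estimation-noise control for classification images.

    Applies, in order: the 4th-order Butterworth spatial window (half-max
    radius ``spatial_hwhm`` mm), the 4th-order Butterworth frequency window
    (half-max radius ``freq_radius`` cyc/mm) with the imaginary spectrum
    zeroed to enforce symmetry, and optionally averaging over one-pixel-wide
    radial annuli.
    """
    img = ci.image * _butterworth(radius_grid(N_IMAGE, PIXEL_MM), spatial_hwhm)
    w_hat = fft_centered(img).real * _butterworth(
        radial_freq_grid(N_IMAGE, PIXEL_MM), freq_radius
    )
    img = ifft_centered(w_hat).real
    if radial:
        img = _radial_band_average(img)
    return replace(ci, image=img, smoothed=True)


def _radial_bins(values: np.ndarray) -> RadialSpectrum:
    f = radial_freq_grid(N_IMAGE, PIXEL_MM)
    idx = np.rint(f / FREQ_STEP).astype(int).ravel()
    sums = np.bincount(idx, weights=values.ravel())
    counts = np.bincount(idx)
    means = sums / counts
    freqs = np.arange(len(means)) * FREQ_STEP
    return RadialSpectrum(freqs, means)


def classification_spectrum(ci: ClassificationImage | np.ndarray) -> RadialSpectrum:
    """Radially averaged spectrum of a classification image, HU^-1 mm^2.

    The FT is taken with the central pixel at the phase origin and multiplied
    by the pixel area; imaginary parts average out over the symmetric bins,
    so only the real part is binned.
    """
    img = ci.image if isinstance(ci, ClassificationImage) else np.asarray(ci, float)
    w_hat = fft_centered(img) * PIXEL_AREA_MM2
    return _radial_bins(w_hat.real)


def spectral_features(ci: ClassificationImage | np.ndarray) -> SpectralFeatures:
    """Integrated power and power-weighted mean frequency below 0.35 cyc/mm."""
    img = ci.image if isinstance(ci, ClassificationImage) else np.asarray(ci, float)
    w_hat = fft_centered(img) * PIXEL_AREA_MM2
    f = radial_freq_grid(N_IMAGE, PIXEL_MM)
    mask = f < FEATURE_FMAX
    power = np.abs(w_hat) ** 2
    ip = FREQ_STEP**2 * float(power[mask].sum())
    if ip == 0:
        raise ValueError("no spectral power below the feature cutoff")
    mf = FREQ_STEP**2 * float((f[mask] * power[mask]).sum()) / ip
    return SpectralFeatures(integrated_power=ip, mean_frequency=mf)


def _snr_parts(w: np.ndarray, condition: Condition, theta: float):
    mu_t, mu_a = condition.mean_images(theta)
    dmu = mu_t - mu_a
    den = condition.sigma_hat() + condition.display.quant_variance
    w_hat = fft_centered(w)
    drho = float((w * dmu).sum())
    var = FREQ_STEP**2 * float((den * np.abs(w_hat) ** 2).sum())
    # covariance times template, spatial domain (for the analytic gradient)
    cw = ifft_centered(den * w_hat).real / PIXEL_MM**2
    return dmu, drho, var, cw


def sampling_efficiency(
    ci: ClassificationImage | Template | np.ndarray, condition: Condition, theta: float
) -> float:
    """Squared ratio of the template's SNR to the Ideal Observer's SNR."""
    w = _as_weights(ci)
    mu_t, mu_a = condition.mean_images(theta)
    snr_w = template_snr(
        Template(w), mu_t, mu_a, condition.noise, condition.apod, condition.display
    )
    w_io = io_template(mu_t, mu_a, condition.noise, condition.apod, condition.display)
    snr_io = template_snr(w_io, mu_t, mu_a, condition.noise, condition.apod, condition.display)
    return float((snr_w / snr_io) ** 2)


def _as_weights(obj) -> np.ndarray:
    if isinstance(obj, ClassificationImage):
        return obj.image
    if isinstance(obj, Template):
        return obj.weights
    return np.asarray(obj, float)


def _perturbation_directions_value(h: np.ndarray) -> np.ndarray:
    """Inner product of a spatial field with every windowed frequency-delta
    perturbation direction, evaluated for all (k,l) at once.

    A unit perturbation of the frequency form (which carries the pixel-area
    factor) at bin (k,l) maps to the spatial direction
    ``W_s * Re(ifft_centered(delta_kl)) / A_pix``; summing it against ``h``
    for every bin is a single FFT of ``W_s * h``.
    """
    return fft_centered(h).real / (N_IMAGE**2 * PIXEL_AREA_MM2)


def differential_sampling_efficiency(
    ci: ClassificationImage | Template | np.ndarray,
    condition: Condition,
    theta: float,
    method: str = "analytic",
    spatial_hwhm: float = SPATIAL_HWHM_MM,
    eps: float | None = None,
) -> RadialSpectrum:
    """Per-frequency gradient of sampling efficiency, radially averaged.

    Each perturbation is a delta at one frequency bin of the template's
    frequency form, symmetrized (imaginary part zeroed in the spatial
    domain) and multiplied by the spatial window before evaluation.
    ``method='analytic'`` differentiates the sampling-efficiency quadratic
    form in closed form; ``'finite'`` uses central differences with a step
    chosen by the 1%-template-SD rule (see :func:`fd_gradient_at`), and is
    considerably slower.
    """
    w = _as_weights(ci)
    if method == "analytic":
        grad2d = analytic_gradient_2d(w, condition, theta, spatial_hwhm)
    elif method == "finite":
        grad2d = np.zeros((N_IMAGE, N_IMAGE))
        idx = [(k, l) for k in range(N_IMAGE) for l in range(N_IMAGE)]
        vals = fd_gradient_at(w, condition, theta, idx, spatial_hwhm, eps)
        for (k, l), v in zip(idx, vals):
            grad2d[k, l] = v
    else:
        raise ValueError("method must be 'analytic' or 'finite'")
    return _radial_bins(grad2d)


def analytic_gradient_2d(
    w: np.ndarray, condition: Condition, theta: float, spatial_hwhm: float = SPATIAL_HWHM_MM
) -> np.ndarray:
    """Closed-form gradient of sampling efficiency over all frequency bins."""
    dmu, drho, var, cw = _snr_parts(w, condition, theta)
    mu_t, mu_a = condition.mean_images(theta)
    w_io = io_template(mu_t, mu_a, condition.noise, condition.apod, condition.display)
    snr_io2 = (
        template_snr(w_io, mu_t, mu_a, condition.noise, condition.apod, condition.display) ** 2
    )
    # d eta / d w (spatial), for eta = (w.dmu)^2 / (w.Cw * snr_io^2)
    g = (2.0 * drho / var) * (dmu - (drho / var) * cw) / snr_io2
    window = _butterworth(radius_grid(N_IMAGE, PIXEL_MM), spatial_hwhm)
    return _perturbation_directions_value(window * g)


def choose_epsilon(w: np.ndarray, direction: np.ndarray, sd_tol: float = 0.01) -> float:
    """Largest perturbation amplitude changing the template SD by ``sd_tol``.

    The pixel-wise SD of ``w + eps*d`` is a quadratic in ``eps``, so the
    bound is solved in closed form rather than by search.
    """
    wc = w - w.mean()
    dc = direction - direction.mean()
    s2 = float((wc**2).mean())
    cross = float((wc * dc).mean())
    d2 = float((dc**2).mean())
    if d2 == 0:
        raise ValueError("degenerate (zero) perturbation direction")
    target = s2 * (1.0 + sd_tol) ** 2
    # d2 eps^2 + 2 cross eps + (s2 - target) = 0; take the positive root
    disc = cross**2 - d2 * (s2 - target)
    return float((-cross + np.sqrt(disc)) / d2)


def fd_gradient_at(
    w: np.ndarray,
    condition: Condition,
    theta: float,
    indices: list[tuple[int, int]],
    spatial_hwhm: float = SPATIAL_HWHM_MM,
    eps: float | None = None,
) -> list[float]:
    """Central-difference differential sampling efficiency at chosen bins.

    ``eps`` (frequency-form units, HU^-1 mm^2) defaults to 1% of the per-bin
    bound from the 1%-template-SD rule — comfortably inside the rule while
    small enough for the central difference to resolve the limit; an explicit
    ``eps`` exceeding the bound is rejected.
    """
    window = _butterworth(radius_grid(N_IMAGE, PIXEL_MM), spatial_hwhm)
    out = []
    for k, l in indices:
        delta = np.zeros((N_IMAGE, N_IMAGE), dtype=complex)
        delta[k, l] = 1.0
        d_spatial = window * ifft_centered(delta).real / PIXEL_AREA_MM2
        e_max = choose_epsilon(w, d_spatial)
        if eps is not None and eps > e_max:
            raise ValueError("eps perturbs the template SD by more than 1%")
        e = eps if eps is not None else 0.01 * e_max
        hi = sampling_efficiency(w + e * d_spatial, condition, theta)
        lo = sampling_efficiency(w - e * d_spatial, condition, theta)
        out.append((hi - lo) / (2.0 * e))
    return out
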