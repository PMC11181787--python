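"""Parametric lesion objects for the three discrimination tasks.

Three two-class tasks are defined, each discriminating a "malignant" from a
"benign" radially symmetric lesion profile on a fine sampling grid:

* **T1 (size)** — a 3 mm-diameter nodule versus one enlarged by ``theta``
  (= delta-R, mm).
* **T2 (edge sharpness)** — a 5 mm nodule versus one whose edge decays with an
  inflated scale ``sigma_L + theta`` (theta = delta-sigma, mm).
* **T3 (interior uniformity)** — a 5 mm nodule versus one whose interior is
  depressed and whose outer annulus is raised by ``L * theta / 2`` HU
  (theta = delta-C, dimensionless).

The benign profile is ``s0(r) = B + L * Phi((R_L - r) / sigma_L)`` with
``Phi`` the standard normal CDF, lesion intensity ``L = 200`` HU on an air
background ``B = -1000`` HU.  Objects are sampled at 9x the final pixel pitch
so that the imaging chain can band-limit and decimate them realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .gridspec import (
    FINE_PITCH_MM,
    N_FINE,
    fft_centered,
    radial_freq_grid,
    radius_grid,
)

__all__ = [
    "TaskSpec",
    "FineGrid",
    "Spectrum2D",
    "make_benign_object",
    "make_malignant_object",
    "difference_object",
    "object_spectrum",
    "spectral_mean_frequency",
    "radial_profile",
]

TASK_IDS = ("T1", "T2", "T3")
#: base lesion radius (mm) per task
BASE_RADIUS = {"T1": 1.5, "T2": 2.5, "T3": 2.5}
INTERIOR_FRACTION = 0.71
EDGE_SCALE_MM = 0.25
LESION_HU = 200.0
BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class TaskSpec:
    """One discrimination task at a specific task-parameter value.

    ``theta`` is delta-R (mm) for T1, delta-sigma (mm) for T2 and delta-C
    (dimensionless) for T3.
    """

    task_id: str
    theta: float
    base_radius: float = 0.0
    interior_radius: float = 0.0
    edge_scale: float = EDGE_SCALE_MM
    lesion_intensity: float = LESION_HU
    background: float = BACKGROUND_HU

    def __post_init__(self):
        if self.task_id not in TASK_IDS:
            raise ValueError(f"unknown task_id {self.task_id!r}; expected one of {TASK_IDS}")
        if self.edge_scale <= 0:
            raise ValueError("edge_scale must be positive")
        if self.theta < 0:
            raise ValueError("task parameter theta must be non-negative")
        if self.base_radius == 0.0:
            object.__setattr__(self, "base_radius", BASE_RADIUS[self.task_id])
        if self.interior_radius == 0.0:
            object.__setattr__(self, "interior_radius", INTERIOR_FRACTION * self.base_radius)

    def with_theta(self, theta: float) -> "TaskSpec":
        return replace(self, theta=theta)


@dataclass(frozen=True)
class FineGrid:
    """A 2D object sampled on the oversampled grid (HU), lesion at N//2."""

    values: np.ndarray
    pitch: float = FINE_PITCH_MM

    @property
    def extent(self) -> float:
        return self.values.shape[0] * self.pitch

    def minus_background(self, background: float = BACKGROUND_HU) -> "FineGrid":
        """The lesion-only component, decaying to zero far from the center."""
        return FineGrid(self.values - background, self.pitch)


@dataclass(frozen=True)
class Spectrum2D:
    """Discrete Fourier transform of a centered object.

    ``values`` is complex, in unshifted FFT ordering, with the lesion center
    at the phase origin; for the symmetric objects built here the imaginary
    part is zero to numerical precision.
    """

    values: np.ndarray
    pitch: float

    @property
    def radial_freq(self) -> np.ndarray:
        return radial_freq_grid(self.values.shape[0], self.pitch)

    @property
    def real_part(self) -> np.ndarray:
        return self.values.real

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def _radii(n: int, pitch: float) -> np.ndarray:
    return radius_grid(n, pitch)


def make_benign_object(spec: TaskSpec, n: int = N_FINE, pitch: float = FINE_PITCH_MM) -> FineGrid:
    """Benign lesion profile ``B + L * Phi((R_L - r) / sigma_L)``."""
    r = _radii(n, pitch)
    values = spec.background + spec.lesion_intensity * norm.cdf(
        (spec.base_radius - r) / spec.edge_scale
    )
    return FineGrid(values, pitch)


def make_malignant_object(spec: TaskSpec, n: int = N_FINE, pitch: float = FINE_PITCH_MM) -> FineGrid:
    """Malignant lesion profile for the task's feature perturbation."""
    r = _radii(n, pitch)
    B, L, sig = spec.background, spec.lesion_intensity, spec.edge_scale
    if spec.task_id == "T1":
        values = B + L * norm.cdf((spec.base_radius + spec.theta - r) / sig)
    elif spec.task_id == "T2":
        values = B + L * norm.cdf((spec.base_radius - r) / (sig + spec.theta))
    else:  # T3
        base = norm.cdf((spec.base_radius - r) / sig)
        inner = norm.cdf((spec.interior_radius - r) / sig)
        values = B + L * base + L * spec.theta * (0.5 * base - inner)
    return FineGrid(values, pitch)


def difference_object(spec: TaskSpec, n: int = N_FINE, pitch: float = FINE_PITCH_MM) -> FineGrid:
    """Malignant-minus-benign object; background-free by construction."""
    mal = make_malignant_object(spec, n, pitch)
    ben = make_benign_object(spec, n, pitch)
    return FineGrid(mal.values - ben.values, pitch)


def object_spectrum(grid: FineGrid) -> Spectrum2D:
    """Discrete FT of a centered object, with the lesion center at the phase
    origin so symmetric inputs have (numerically) zero imaginary part."""
    return Spectrum2D(fft_centered(grid.values), grid.pitch)


def spectral_mean_frequency(
    spectrum: Spectrum2D,
    weighting: str = "amplitude",
    fmax: float | None = None,
) -> float:
    """Spectral-weighted mean radial frequency, cyc/mm.

    ``weighting='amplitude'`` uses |S| (the convention for object spectra);
    ``'power'`` uses |S|^2 (the convention for classification-image features).
    ``fmax`` optionally restricts the sum to radial frequencies below it.
    """
    if weighting == "amplitude":
        w = spectrum.magnitude
    elif weighting == "power":
        w = spectrum.magnitude**2
    else:
        raise ValueError("weighting must be 'amplitude' or 'power'")
    f = spectrum.radial_freq
    if fmax is not None:
        mask = f < fmax
        w = np.where(mask, w, 0.0)
    total = w.sum()
    if total == 0:
        raise ValueError("spectrum has no weight; mean frequency undefined")
    return float((f * w).sum() / total)


def radial_profile(grid: FineGrid, n_bins: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Radially binned profile (bin-center radius mm, mean value HU)."""
    r = _radii(grid.values.shape[0], grid.pitch).ravel()
    v = grid.values.ravel()
    if n_bins is None:
        n_bins = grid.values.shape[0] // 2
    edges = np.linspace(0.0, grid.extent / 2.0, n_bins + 1)
    idx = np.digitize(r, edges) - 1
    keep = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[keep], weights=v[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        prof = sums / counts
    return centers[counts > 0], prof[counts > 0]
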