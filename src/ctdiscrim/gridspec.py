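"""Shared sampling-grid and Fourier conventions.

The simulated scanner reconstructs a 350 mm field of view on a 512-pixel
array, giving an image pixel of 350/512 = 0.68359375 mm.  All psychophysical
stimuli live on a 128x128 crop of that grid (87.5 mm square).  Objects are
synthesized on a 9x-oversampled 1152x1152 grid with the same physical extent,
so one coarse pixel covers exactly nine fine samples in each direction.

Spatial arrays are stored "centered": the lesion center sits at index N//2 in
both axes.  Frequency-domain arrays use unshifted FFT ordering internally;
``fft_centered``/``ifft_centered`` move between the two so that a symmetric,
centered object has a purely real spectrum.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: final image pixel pitch, mm (350 mm FOV / 512 pixels)
PIXEL_MM: float = 350.0 / 512.0
#: final image pixel area, mm^2
PIXEL_AREA_MM2: float = PIXEL_MM**2
#: stimulus array size (pixels per side)
N_IMAGE: int = 128
#: oversampling factor of the object grid
OVERSAMPLE: int = 9
#: object (fine) grid size
N_FINE: int = N_IMAGE * OVERSAMPLE
#: fine-grid pitch, mm
FINE_PITCH_MM: float = PIXEL_MM / OVERSAMPLE
#: physical side length of both grids, mm
EXTENT_MM: float = N_IMAGE * PIXEL_MM
#: frequency-sample width of the image grid, cyc/mm
FREQ_STEP: float = 1.0 / (N_IMAGE * PIXEL_MM)
#: Nyquist frequency of the image grid, cyc/mm
F_NYQUIST: float = 1.0 / (2.0 * PIXEL_MM)


@lru_cache(maxsize=8)
def radius_grid(n: int, pitch: float) -> np.ndarray:
    """Distance (mm) of each sample from the grid center at index ``n // 2``."""
    x = (np.arange(n) - n // 2) * pitch
    return np.hypot(x[:, None], x[None, :])


@lru_cache(maxsize=8)
def radial_freq_grid(n: int, pitch: float) -> np.ndarray:
    """Radial frequency magnitude (cyc/mm) in unshifted FFT ordering."""
    f = np.fft.fftfreq(n, d=pitch)
    return np.hypot(f[:, None], f[None, :])


def fft_centered(a: np.ndarray) -> np.ndarray:
    """2D FFT of a centered spatial array (phase origin at index n//2).

    Output is in unshifted FFT frequency ordering; a real array symmetric
    about its center transforms to a (numerically) real spectrum.
    """
    return np.fft.fft2(np.fft.ifftshift(a))


def ifft_centered(A: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft_centered`; returns a centered spatial array."""
    return np.fft.fftshift(np.fft.ifft2(A))
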