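"""Closed-form Gaussian band-shape helpers.

A Raman band is modelled as ``A * exp(-(x - mu)^2 / (2 sigma^2))`` with the
width expressed as full width at half maximum (FWHM = 2 sqrt(2 ln 2) sigma).
The full area is ``A * FWHM * sqrt(pi / (4 ln 2))`` and the area restricted to
a wavenumber window follows from the error function.  These closed forms are
the independent oracle for every trapezoid/fit computation in the package.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

# FWHM = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
# area = amplitude * fwhm * AREA_FACTOR
AREA_FACTOR = float(np.sqrt(np.pi / (4.0 * np.log(2.0))))


def gaussian(x, center: float, fwhm: float, amplitude: float):
    """Evaluate one Gaussian band on wavenumber grid ``x``."""
    sigma = fwhm * FWHM_TO_SIGMA
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gaussian_area(amplitude: float, fwhm: float) -> float:
    """Total area under one Gaussian band (the AUGC closed form)."""
    return amplitude * fwhm * AREA_FACTOR


def gaussian_window_area(
    amplitude: float, center: float, fwhm: float, lo: float, hi: float
) -> float:
    """Exact area of one Gaussian band restricted to ``[lo, hi]``."""
    sigma = fwhm * FWHM_TO_SIGMA
    s2 = sigma * np.sqrt(2.0)
    return float(
        amplitude
        * sigma
        * np.sqrt(2.0 * np.pi)
        * 0.5
        * (erf((hi - center) / s2) - erf((lo - center) / s2))
    )


def sum_of_gaussians(x, params) -> np.ndarray:
    """Sum of bands given an iterable of ``(center, fwhm, amplitude)``."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for center, fwhm, amplitude in params:
        out += gaussian(x, center, fwhm, amplitude)
    return out


def sum_window_area(params, lo: float, hi: float) -> float:
    """Exact windowed area of a sum of bands ``(center, fwhm, amplitude)``."""
    return float(
        sum(gaussian_window_area(a, c, f, lo, hi) for c, f, a in params)
    )
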