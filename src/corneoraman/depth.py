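"""Skin-surface detection, SC thickness and depth normalisation.

The skin surface is the position where the keratin profile (Raman intensity
at 1655 cm-1 as a function of acquisition depth) first reaches half of its
maximum coming from outside the skin; the crossing is refined by linear
interpolation between the bracketing samples.

The stratum corneum (SC) thickness follows the water-gradient criterion of
Crowther: moving inward from the surface, the first derivative of the water
mass % profile (in % per um) rises through the steep mid-SC gradient and
decays to 0.5 at the SC/SG boundary.  The implementation smooths the profile
with a 3-point moving average, takes centred finite differences and locates
the falling 0.5-crossing that follows the derivative maximum.  A normalised
convention (threshold on the max-scaled derivative) is selectable.

Metric profiles are then normalised to % SC depth (0% = surface, 100% =
SC/SG boundary) and linearly interpolated to 10% increments; points outside
the measured span are flagged missing (NaN), never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .exceptions import FitError, ValidationError

__all__ = [
    "SurfaceEstimate",
    "ScProfile",
    "find_surface",
    "sc_thickness",
    "normalize_and_resample",
    "percent_grid",
]


@dataclass(frozen=True)
class SurfaceEstimate:
    """Skin-surface position in acquisition coordinates."""

    surface_um: float
    half_max: float


@dataclass
class ScProfile:
    """Per-volunteer metric profiles on the normalised % SC depth grid."""

    volunteer_id: str
    thickness_um: float
    grid_pct: np.ndarray
    values: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.grid_pct = np.asarray(self.grid_pct, dtype=float)
        if self.thickness_um <= 0:
            raise ValidationError("SC thickness must be > 0")
        for name, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.size != self.grid_pct.size:
                raise ValidationError(f"profile {name!r} does not match the grid")
            self.values[name] = v


def percent_grid(step_pct: float = 10.0) -> np.ndarray:
    """The normalised depth grid {0, step, ..., 100} %."""
    n = int(round(100.0 / step_pct))
    if not np.isclose(n * step_pct, 100.0):
        raise ValidationError("grid step must divide 100%")
    return np.linspace(0.0, 100.0, n + 1)


def find_surface(depths_um, profile) -> SurfaceEstimate:
    """Locate the skin surface from a keratin intensity depth profile.

    ``profile`` is the (baseline-corrected) 1655 cm-1 intensity at each
    acquisition depth, ordered from outside the skin inward.  The surface is
    the first upward crossing of half the profile maximum, linearly
    interpolated between the bracketing samples.
    """
    z = np.asarray(depths_um, dtype=float)
    y = np.asarray(profile, dtype=float)
    if z.size != y.size or z.size < 3:
        raise ValidationError("profile and depths must align (>= 3 samples)")
    m = float(np.max(y))
    if m <= 0:
        raise FitError("no surface crossing: keratin profile never positive")
    half = m / 2.0
    below = y < half
    for i in range(z.size - 1):
        if below[i] and y[i + 1] >= half:
            frac = (half - y[i]) / (y[i + 1] - y[i])
            return SurfaceEstimate(float(z[i] + frac * (z[i + 1] - z[i])), half)
    raise FitError(
        "no surface crossing: profile never rises through half-maximum "
        "from outside the skin"
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    if window % 2 == 0:
        raise ValidationError("smoothing window must be odd")
    pad = window // 2
    padded = np.concatenate([np.repeat(y[0], pad), y, np.repeat(y[-1], pad)])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def sc_thickness(
    depths_um,
    water_pct,
    threshold: float = 0.5,
    smooth_window: int = 3,
    convention: str = "percent_per_um",
) -> Tuple[float, Dict]:
    """SC thickness from the water-gradient boundary criterion.

    Parameters
    ----------
    depths_um : surface-aligned depths (0 = skin surface), strictly increasing.
    water_pct : water mass % at each depth, from the SC into the SG.
    threshold : derivative threshold; 0.5 % per um by default.
    convention : ``'percent_per_um'`` thresholds the physical derivative,
        ``'normalized'`` thresholds the max-scaled derivative.

    Returns ``(thickness_um, diagnostics)``; raises :class:`FitError` with
    the diagnostic profile attached when the derivative never falls through
    the threshold beyond its maximum.
    """
    z = np.asarray(depths_um, dtype=float)
    w = np.asarray(water_pct, dtype=float)
    ok = np.isfinite(w)
    z, w = z[ok], w[ok]
    if z.size < 5:
        raise ValidationError("need >= 5 finite water samples")
    if np.any(np.diff(z) <= 0):
        raise ValidationError("depths must be strictly increasing")
    ws = _smooth(w, smooth_window)
    dz = np.gradient(ws, z)  # centred differences, one-sided at the ends
    deriv = dz.copy()
    if convention == "normalized":
        peak = float(np.max(np.abs(deriv)))
        if peak <= 0:
            raise FitError("flat water profile; no gradient boundary")
        deriv = deriv / peak
    elif convention != "percent_per_um":
        raise ValidationError(f"unknown thickness convention {convention!r}")
    diagnostics = {
        "depths_um": z, "water_pct": w, "smoothed": ws, "derivative": deriv,
    }
    # interior samples only: one-sided end estimates are unreliable
    i0, i1 = 1, z.size - 1
    imax = i0 + int(np.argmax(deriv[i0:i1]))
    if deriv[imax] < threshold:
        raise FitError(
            f"water-profile derivative never reaches {threshold:g}; "
            f"max {deriv[imax]:.3g} at {z[imax]:.1f} um",
        )
    for i in range(imax, i1 - 1):
        if deriv[i] >= threshold > deriv[i + 1]:
            frac = (deriv[i] - threshold) / (deriv[i] - deriv[i + 1])
            t = float(z[i] + frac * (z[i + 1] - z[i]))
            diagnostics["crossing_index"] = i
            return t, diagnostics
    err = FitError(
        "water-profile derivative never falls through the threshold inside "
        "the scanned range"
    )
    err.diagnostics = diagnostics
    raise err


def normalize_and_resample(
    depths_um,
    values,
    surface_um: float,
    thickness_um: float,
    grid_step_pct: float = 10.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Resample a metric depth series onto the {0, 10, ..., 100}% SC grid.

    ``depths_um`` are acquisition depths; ``surface_um`` shifts them so the
    surface is 0, and ``thickness_um`` scales to % SC depth.  Values are
    linearly interpolated; grid points outside the measured span (or with no
    finite neighbours) are NaN.
    """
    z = np.asarray(depths_um, dtype=float) - surface_um
    v = np.asarray(values, dtype=float)
    if thickness_um <= 0:
        raise ValidationError("thickness must be > 0")
    ok = np.isfinite(v)
    z, v = z[ok], v[ok]
    grid = percent_grid(grid_step_pct)
    out = np.full(grid.size, np.nan)
    if z.size < 2:
        return grid, out
    zq = grid / 100.0 * thickness_um
    inside = (zq >= z[0] - 1e-9) & (zq <= z[-1] + 1e-9)
    out[inside] = np.interp(zq[inside], z, v)
    return grid, out
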