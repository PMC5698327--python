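"""Integration windows and trapezoidal area-under-curve computation.

The conformational and hydration indicators are ratios of areas integrated
over fixed wavenumber windows.  The registry below carries the standard
windows: the S-S stretch conformers (474-578 cm-1 with the
gauche-gauche-gauche sub-window 474-508), the cysteine C-S band (690-712),
the tyrosine Fermi doublet (816-838 buried / 838-874 exposed), the C-C
skeletal alpha/beta bands (924-946 / 952-966) and the HWN keratin CH
(2910-2965) and water OH (3350-3550) windows.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterator, Mapping, Tuple, Union

import numpy as np

from .exceptions import ValidationError
from .spectra import BandWindow, Spectrum

log = logging.getLogger(__name__)

__all__ = ["WindowRegistry", "default_windows", "auc"]

_DEFAULTS: Tuple[Tuple[str, float, float], ...] = (
    ("ss_ggg", 474.0, 508.0),
    ("ss_total", 474.0, 578.0),
    ("cs_cys", 690.0, 712.0),
    ("tyr_buried", 816.0, 838.0),
    ("tyr_exposed", 838.0, 874.0),
    ("alpha_cc", 924.0, 946.0),
    ("beta_cc", 952.0, 966.0),
    ("keratin_ch", 2910.0, 2965.0),
    ("water_oh", 3350.0, 3550.0),
)


class WindowRegistry(Mapping):
    """Named integration windows; immutable mapping ``name -> BandWindow``."""

    def __init__(self, windows=None):
        if windows is None:
            windows = [BandWindow(n, lo, hi) for n, lo, hi in _DEFAULTS]
        table: Dict[str, BandWindow] = {}
        for w in windows:
            if w.name in table:
                raise ValidationError(f"duplicate window name {w.name!r}")
            table[w.name] = w
        self._table = table

    def __getitem__(self, name: str) -> BandWindow:
        return self._table[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def replace(self, name: str, lo: float, hi: float) -> "WindowRegistry":
        new = dict(self._table)
        new[name] = BandWindow(name, lo, hi)
        return WindowRegistry(list(new.values()))

    def to_dict(self) -> Dict[str, Tuple[float, float]]:
        return {n: (w.lo, w.hi) for n, w in self._table.items()}


def default_windows() -> WindowRegistry:
    return WindowRegistry()


def auc(spectrum: Spectrum, window: Union[BandWindow, Tuple[float, float]]) -> float:
    """Trapezoidal area under ``spectrum`` over ``window`` (counts * cm-1).

    Boundary intensities are obtained by linear interpolation when the window
    edges fall between grid points, making the result exact for the
    piecewise-linear data model and additive over adjacent windows.
    The spectrum is expected to be baseline-corrected; negative intensities
    are integrated as-is (a negative total is logged, not clipped).
    """
    if isinstance(window, BandWindow):
        name, lo, hi = window.name, window.lo, window.hi
    else:
        lo, hi = float(window[0]), float(window[1])
        name = f"[{lo:g},{hi:g}]"
        if lo >= hi:
            raise ValidationError(f"reversed integration bounds [{lo:g}, {hi:g}]")
    x = spectrum.wavenumbers
    y = spectrum.intensities
    if lo < x[0] or hi > x[-1]:
        raise ValidationError(
            f"window {name} outside spectrum span [{x[0]:g}, {x[-1]:g}]"
        )
    inner = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]))
    area = float(np.trapezoid(ys, xs))
    if area < 0:
        # expected for signal-free (air) spectra after baseline removal
        log.debug("negative AUC %.4g over window %s", area, name)
    return area
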