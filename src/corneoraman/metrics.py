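"""Per-spectrum conformational and hydration indicators.

Eight indicators are computed per depth:

==================  ==========================================================
beta_alpha_cc       beta-sheet/alpha-helix from the C-C skeletal bands,
                    AUC(952-966) / AUC(924-946)
beta_alpha_amide1   (beta-sheet + turns/random coil)/alpha-helix from the
                    Amide I deconvolution, (AUGC_1670 + AUGC_1685)/AUGC_1655
ss_stability        gauche-gauche-gauche fraction of all disulphide bonds,
                    AUC(474-508) / AUC(474-578)
cs_ss               free-cysteine C-S over disulphide S-S,
                    AUC(690-712) / AUC(474-578)
tyr_ratio           buried/exposed tyrosine, AUC(816-838) / AUC(838-874)
ch3_position        fitted center of the 2930 cm-1 CH3 band (cm-1)
water_mass_pct      water mass %, from R = AUC(3350-3550)/AUC(2910-2965)
bound_water_ratio   weakly/strongly bound water, AUGC_3458 / AUGC_3277
==================  ==========================================================

All AUC ratios are scale invariant; ``ss_stability`` lies in [0, 1] for
non-negative spectra because its numerator window is a sub-window of its
denominator.  Ratios with non-positive denominators return NaN (the
undefined-ratio flag).

The water calibration maps the OH/keratin area ratio R to mass % with the
saturating form ``water% = 100 R / (R + c)``: the mass-balance shape forced
by water/(water + protein) logic, strictly increasing in R, 0 at R = 0 and
approaching 100 as R grows.  The constant ``c`` absorbs the instrument
response and is configurable; absolute water percentages are therefore
calibration-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .exceptions import ValidationError
from .preprocess import AnchorScheme, remove_linear_baseline
from .spectra import Spectrum
from .windows import WindowRegistry, auc, default_windows

__all__ = [
    "METRIC_NAMES",
    "MetricVector",
    "WaterCalibration",
    "beta_alpha_cc",
    "ss_stability",
    "cs_ss",
    "tyr_ratio",
    "water_ratio",
    "water_mass_pct",
]

METRIC_NAMES = (
    "beta_alpha_cc",
    "beta_alpha_amide1",
    "ss_stability",
    "cs_ss",
    "tyr_ratio",
    "ch3_position",
    "water_mass_pct",
    "bound_water_ratio",
)


@dataclass(frozen=True)
class WaterCalibration:
    """Calibration constant of the OH/keratin ratio -> water mass % mapping."""

    c: float = 1.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValidationError(f"calibration constant must be > 0, got {self.c:g}")

    def to_mass_pct(self, ratio: float) -> float:
        if ratio < 0:
            return float("nan")
        return 100.0 * ratio / (ratio + self.c)

    def to_ratio(self, mass_pct: float) -> float:
        """Inverse mapping (used by the synthetic generator)."""
        if not 0 <= mass_pct < 100:
            raise ValidationError("water mass % must lie in [0, 100)")
        return self.c * mass_pct / (100.0 - mass_pct)


@dataclass
class MetricVector:
    """The eight per-spectrum indicators (NaN = undefined/flagged)."""

    beta_alpha_cc: float = float("nan")
    beta_alpha_amide1: float = float("nan")
    ss_stability: float = float("nan")
    cs_ss: float = float("nan")
    tyr_ratio: float = float("nan")
    ch3_position: float = float("nan")
    water_mass_pct: float = float("nan")
    bound_water_ratio: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _segment(spectrum: Spectrum, anchors: Optional[AnchorScheme], group: str) -> Spectrum:
    """Baseline-correct the group's band segment, or pass through if the
    caller already removed the baseline (``anchors=None``)."""
    if anchors is None:
        return spectrum
    return remove_linear_baseline(spectrum, anchors[group])


def _ratio(num: float, den: float) -> float:
    if den <= 0:
        return float("nan")
    return num / den


def beta_alpha_cc(
    spectrum: Spectrum,
    anchors: Optional[AnchorScheme] = None,
    windows: Optional[WindowRegistry] = None,
) -> float:
    """beta-sheet/alpha-helix C-C ratio, AUC(952-966)/AUC(924-946)."""
    w = windows or default_windows()
    seg = _segment(spectrum, anchors, "cc")
    return _ratio(auc(seg, w["beta_cc"]), auc(seg, w["alpha_cc"]))


def ss_stability(
    spectrum: Spectrum,
    anchors: Optional[AnchorScheme] = None,
    windows: Optional[WindowRegistry] = None,
) -> float:
    """gauche-gauche-gauche fraction of total S-S, AUC(474-508)/AUC(474-578)."""
    w = windows or default_windows()
    seg = _segment(spectrum, anchors, "ss")
    return _ratio(auc(seg, w["ss_ggg"]), auc(seg, w["ss_total"]))


def cs_ss(
    spectrum: Spectrum,
    anchors: Optional[AnchorScheme] = None,
    windows: Optional[WindowRegistry] = None,
) -> float:
    """Cysteine C-S over disulphide S-S, AUC(690-712)/AUC(474-578)."""
    w = windows or default_windows()
    num_seg = _segment(spectrum, anchors, "cs")
    den_seg = _segment(spectrum, anchors, "ss")
    return _ratio(auc(num_seg, w["cs_cys"]), auc(den_seg, w["ss_total"]))


def tyr_ratio(
    spectrum: Spectrum,
    anchors: Optional[AnchorScheme] = None,
    windows: Optional[WindowRegistry] = None,
) -> float:
    """Buried/exposed tyrosine, AUC(816-838)/AUC(838-874)."""
    w = windows or default_windows()
    seg = _segment(spectrum, anchors, "tyr")
    return _ratio(auc(seg, w["tyr_buried"]), auc(seg, w["tyr_exposed"]))


def water_ratio(
    spectrum_hwn: Spectrum, windows: Optional[WindowRegistry] = None
) -> float:
    """OH/keratin area ratio R = AUC(3350-3550)/AUC(2910-2965).

    Expects a baseline-corrected HWN spectrum; NaN when the keratin area is
    non-positive.
    """
    w = windows or default_windows()
    return _ratio(auc(spectrum_hwn, w["water_oh"]), auc(spectrum_hwn, w["keratin_ch"]))


def water_mass_pct(
    spectrum_hwn: Spectrum,
    calibration: WaterCalibration = WaterCalibration(),
    windows: Optional[WindowRegistry] = None,
) -> float:
    """Water mass % from the calibrated OH/keratin area ratio."""
    r = water_ratio(spectrum_hwn, windows)
    if not np.isfinite(r):
        return float("nan")
    return calibration.to_mass_pct(r)
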