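"""Synthetic depth-resolved Raman cohorts with known ground truth.

The in vivo data this analysis was designed for cannot be shared, so the
generator builds cohorts whose *statistical structure* matches the study
design: 11 volunteers x 10 lateral positions x 21 depths (0-40 um, 2 um
step), each depth yielding one fingerprint and one HWN spectrum.  Every
spectrum is a sum of Gaussian bands (the keratin/lipid band inventory of the
stratum corneum) on top of a linear baseline, a broad fluorescence hump
(fingerprint) or a two-gradient piecewise-linear background (HWN), plus
seeded additive noise.

Depth dependence is imposed on the *metric trajectories* -- the eight
conformational/hydration indicators as piecewise-linear functions of % SC
depth -- and band amplitudes are solved from them, so the generator's truth
table and the analysis definitions are self-consistent by construction.
Default trajectory endpoints follow the qualitative shapes reported for
healthy forearm skin: the gauche-gauche-gauche disulphide fraction rises
from a deep plateau ~0.3 to ~0.8 at the surface, the free-cysteine C-S/S-S
ratio peaks (~0.12) near 70% depth with a 0.08 plateau at 40-10%, the
buried/exposed tyrosine ratio dips to ~0.3 in mid-SC and rebounds toward
~0.8 at the surface, water mass % falls from ~40 at the SC/SG boundary to
~15 near the surface, and the weakly/strongly bound water ratio is U-shaped
with its minimum around 30% depth.

The air/skin transition is modelled as a logistic attenuation of all tissue
bands across the true surface, and the water profile is built so that its
physical gradient just inside the SC/SG boundary decays through the
0.5 %/um Crowther criterion exactly at the true boundary -- the landmark the
thickness estimator is defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._gaussian import gaussian, gaussian_area, sum_of_gaussians, sum_window_area
from .exceptions import ValidationError
from .metrics import METRIC_NAMES, WaterCalibration
from .spectra import Cohort, DepthSeries, Region, Spectrum, VolunteerRecord
from .windows import default_windows

__all__ = [
    "FP_GRID",
    "HWN_GRID",
    "ProfileSpec",
    "NoiseSpec",
    "VolunteerTruth",
    "SyntheticGroundTruth",
    "synth_spectrum",
    "synth_cohort",
]

#: default acquisition grids (1 cm-1 fingerprint, 2 cm-1 HWN)
FP_GRID = np.arange(400.0, 1800.0 + 0.5, 1.0)
HWN_GRID = np.arange(2000.0, 4000.0 + 1.0, 2.0)

#: % SC depth nodes of every default trajectory (0 = surface, 100 = SC/SG)
TRAJ_GRID = np.linspace(0.0, 100.0, 11)

#: default metric trajectories, surface -> boundary
DEFAULT_TRAJECTORIES: Dict[str, np.ndarray] = {
    "ss_stability": np.array(
        [0.80, 0.72, 0.62, 0.52, 0.43, 0.355, 0.315, 0.305, 0.300, 0.298, 0.296]),
    "cs_ss": np.array(
        [0.055, 0.075, 0.079, 0.080, 0.081, 0.090, 0.105, 0.120, 0.115, 0.110, 0.106]),
    "tyr_ratio": np.array(
        [0.78, 0.60, 0.38, 0.31, 0.300, 0.305, 0.33, 0.42, 0.52, 0.60, 0.65]),
    "beta_alpha_cc": np.array(
        [0.246, 0.238, 0.236, 0.2355, 0.235, 0.242, 0.248, 0.254, 0.259, 0.263, 0.266]),
    "beta_alpha_amide1": np.array(
        [0.415, 0.390, 0.388, 0.387, 0.386, 0.420, 0.450, 0.468, 0.470, 0.472, 0.474]),
    "ch3_position": np.array(
        [2928.2, 2928.6, 2929.0, 2929.5, 2930.0, 2930.4, 2930.65, 2930.7,
         2930.5, 2930.2, 2930.0]),
    "bound_water_ratio": np.array(
        [0.95, 0.88, 0.78, 0.75, 0.76, 0.82, 0.90, 0.98, 1.05, 1.12, 1.18]),
}

# band geometry: name -> (center, fwhm); amplitudes are solved per depth
_FP_METRIC_GEOM = {
    "ss_ggg_491": (491.0, 12.0),
    "ss_ggt_525": (525.0, 13.0),
    "ss_tgt_546": (546.0, 14.0),
    "cs_700": (700.0, 8.5),
    "tyr_830": (830.0, 10.0),
    "tyr_850": (850.0, 12.0),
    "cc_938": (938.0, 12.0),
    "cc_960": (960.0, 7.0),
    "amide_1617": (1617.0, 23.0),
    "amide_1655": (1655.0, 30.0),
    "amide_1670": (1670.0, 15.0),
    "amide_1685": (1685.0, 37.0),
}
# fixed fingerprint bands: name -> (center, fwhm, amplitude rel. K/1000)
_FP_FIXED = {
    "cs_620": (620.0, 10.0, 25.0),
    "cs_640": (640.0, 11.0, 35.0),
    "phe_1003": (1003.0, 10.0, 380.0),
    "lipid_1298": (1298.0, 20.0, 260.0),
    "def_1450": (1450.0, 28.0, 330.0),
}
# HWN CH family: name -> (center, fwhm, amplitude rel. K/1000); names match
# the deconvolution model so fitted and true bands can be compared directly
_HWN_CH = {
    "ch2_sym_2850": (2850.0, 24.0, 620.0),
    "ch2_asym_2880": (2880.0, 28.0, 700.0),
    "ch3_sym_2930": (2930.0, 34.0, 1000.0),
    "ch3_asym_2980": (2980.0, 30.0, 360.0),
    "ch_olefinic_3063": (3063.0, 40.0, 190.0),
}
# HWN OH family: relative amplitudes before the water-content scaling;
# the 3458 amplitude is solved from the bound-water trajectory
_HWN_OH = {
    "oh_3180": (3180.0, 90.0, 0.50),
    "oh_strong_3277": (3277.0, 110.0, 1.00),
    "oh_weak_3458": (3458.0, 100.0, None),
    "oh_3550": (3550.0, 120.0, 0.45),
    "oh_free_3630": (3630.0, 95.0, 0.12),
}

# integration windows used when inverting trajectories to amplitudes
_W = default_windows()
_NON_GGG_SPLIT = 0.55  # gauche-gauche-trans share of the non-ggg S-S area


@dataclass(frozen=True)
class WaterProfileSpec:
    """Physical-depth water trajectory with the Crowther boundary signature.

    Water mass % rises from ``surface_pct`` at the skin surface to
    ``boundary_pct`` at the SC/SG boundary.  The final ``ramp_len_um``
    micrometres inside the boundary have slope ``boundary_slope`` (% per um)
    and the SG plateau continues at ``sg_slope``; their midpoint equals the
    0.5 %/um detection threshold, so the derivative criterion lands exactly
    on the true boundary.
    """

    surface_pct: float = 15.0
    boundary_pct: float = 40.0
    boundary_slope: float = 0.95
    sg_slope: float = 0.05
    ramp_len_um: float = 6.0


@dataclass(frozen=True)
class ProfileSpec:
    """Per-metric parametric trajectories over % SC depth."""

    trajectories: Dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_TRAJECTORIES.items()})
    water: WaterProfileSpec = field(default_factory=WaterProfileSpec)

    def __post_init__(self):
        converted = {}
        for name, v in self.trajectories.items():
            v = np.asarray(v, dtype=float)
            if v.size != TRAJ_GRID.size:
                raise ValidationError(
                    f"trajectory {name!r} must have {TRAJ_GRID.size} nodes")
            converted[name] = v
        object.__setattr__(self, "trajectories", converted)
        ss = self.trajectories.get("ss_stability")
        if ss is not None and (np.any(ss < 0) or np.any(ss > 1)):
            raise ValidationError("ss_stability trajectory must stay in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise, background and inter-volunteer variability settings.

    ``sigma_fp``/``sigma_hwn`` are additive per-channel noise levels as a
    fraction of the clean maximum band amplitude of the region (fingerprint
    spectra are acquired ~5x longer, hence less noisy).  All draws are
    reproducible from the seed handed to :func:`synth_cohort`.
    """

    sigma_fp: float = 0.01
    sigma_hwn: float = 0.02
    baseline_offset: Tuple[float, float] = (10.0, 30.0)
    baseline_slope: Tuple[float, float] = (-0.01, 0.01)
    fluorescence_amplitude: Tuple[float, float] = (15.0, 35.0)
    fluorescence_center: float = 1200.0
    fluorescence_fwhm: float = 1600.0
    hwn_hinge_offset: Tuple[float, float] = (5.0, 20.0)
    hwn_hinge_slopes: Tuple[float, float] = (-0.004, 0.004)
    volunteer_cv: float = 0.06
    position_scale_sigma: float = 0.08
    thickness_range_um: Tuple[float, float] = (10.0, 25.0)
    surface_range_um: Tuple[float, float] = (2.5, 5.5)
    transition_width_um: float = 1.2

    def __post_init__(self):
        if self.sigma_fp < 0 or self.sigma_hwn < 0:
            raise ValidationError("noise sigma must be >= 0")
        if self.thickness_range_um[0] <= 0:
            raise ValidationError("SC thickness must be > 0")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        """Zero additive noise; backgrounds and biological variability kept."""
        return cls(sigma_fp=0.0, sigma_hwn=0.0)


@dataclass
class VolunteerTruth:
    """Ground-truth geometry, trajectories and band geometry of one volunteer."""

    volunteer_id: str
    surface_um: float
    thickness_um: float
    k_scale: float
    trajectories: Dict[str, np.ndarray]
    water: WaterProfileSpec
    band_geometry: Dict[str, Tuple[float, float]]  # name -> (center, fwhm)
    fixed_amps: Dict[str, float]

    def metric_at(self, name: str, pct) -> np.ndarray:
        """Trajectory value at % SC depth (clamped beyond the boundary)."""
        return np.interp(pct, TRAJ_GRID, self.trajectories[name])

    def water_at(self, z_rel) -> np.ndarray:
        """Water mass % at depth ``z_rel`` below the true surface (um)."""
        w = self.water
        t = self.thickness_um
        ramp_start = t - w.ramp_len_um
        w_ramp = w.boundary_pct - w.boundary_slope * w.ramp_len_um
        z = np.atleast_1d(np.asarray(z_rel, dtype=float))
        out = np.empty_like(z)
        deep = z >= t
        mid = (z >= ramp_start) & ~deep
        up = ~deep & ~mid
        out[deep] = w.boundary_pct + w.sg_slope * (z[deep] - t)
        out[mid] = w.boundary_pct - w.boundary_slope * (t - z[mid])
        frac = np.clip(z[up], 0.0, None) / max(ramp_start, 1e-9)
        out[up] = w.surface_pct + (w_ramp - w.surface_pct) * frac
        return out if np.ndim(z_rel) else float(out[0])


# ---------------------------------------------------------------------------
# amplitude solvers (trajectory value -> band amplitudes, exact via erf areas)
# ---------------------------------------------------------------------------

def _E(geom: Tuple[float, float], window) -> float:
    """Windowed area of a unit-amplitude band."""
    from ._gaussian import gaussian_window_area

    return gaussian_window_area(1.0, geom[0], geom[1], window.lo, window.hi)


def _solve_two_band(g1, g2, w_num, w_den, ratio, den_area):
    """Amplitudes (a1, a2) with auc(num)/auc(den) = ratio, auc(den) = den_area."""
    m = np.array([[_E(g1, w_num), _E(g2, w_num)],
                  [_E(g1, w_den), _E(g2, w_den)]])
    a = np.linalg.solve(m, np.array([ratio * den_area, den_area]))
    if np.any(a < 0):
        raise ValidationError(
            f"trajectory value {ratio:g} not realisable with non-negative bands")
    return float(a[0]), float(a[1])


def _solve_ss(geoms, fraction, total_area):
    """Amplitudes of the 491/525/546 S-S conformer bands."""
    g491, g525, g546 = geoms
    wg, wt = _W["ss_ggg"], _W["ss_total"]
    col2 = np.array([
        _NON_GGG_SPLIT * _E(g525, wg) + (1 - _NON_GGG_SPLIT) * _E(g546, wg),
        _NON_GGG_SPLIT * _E(g525, wt) + (1 - _NON_GGG_SPLIT) * _E(g546, wt),
    ])
    m = np.array([[_E(g491, wg), col2[0]], [_E(g491, wt), col2[1]]])
    x, y = np.linalg.solve(m, np.array([fraction * total_area, total_area]))
    if x < 0 or y < 0:
        raise ValidationError(f"S-S fraction {fraction:g} not realisable")
    return float(x), float(_NON_GGG_SPLIT * y), float((1 - _NON_GGG_SPLIT) * y)


def _band_params_at(vol: VolunteerTruth, pct: float, z_rel: float,
                    calibration: WaterCalibration):
    """True band parameters (unattenuated, unit position scale) at one depth.

    Returns ``(fp_params, hwn_params)`` as lists of
    ``(name, center, fwhm, amplitude)``.
    """
    K = vol.k_scale
    geo = vol.band_geometry
    tr = lambda name: float(vol.metric_at(name, pct))

    fp: List[Tuple[str, float, float, float]] = []
    # C-C skeletal alpha/beta pair
    a938, a960 = _solve_two_band(geo["cc_938"], geo["cc_960"],
                                 _W["beta_cc"], _W["alpha_cc"],
                                 tr("beta_alpha_cc"), 6.0 * K)
    fp += [("cc_938", *geo["cc_938"], a938), ("cc_960", *geo["cc_960"], a960)]
    # disulphide conformers
    ss_area = 2.9 * K
    a491, a525, a546 = _solve_ss(
        (geo["ss_ggg_491"], geo["ss_ggt_525"], geo["ss_tgt_546"]),
        tr("ss_stability"), ss_area)
    fp += [("ss_ggg_491", *geo["ss_ggg_491"], a491),
           ("ss_ggt_525", *geo["ss_ggt_525"], a525),
           ("ss_tgt_546", *geo["ss_tgt_546"], a546)]
    # free cysteine C-S
    a700 = tr("cs_ss") * ss_area / _E(geo["cs_700"], _W["cs_cys"])
    fp.append(("cs_700", *geo["cs_700"], a700))
    # tyrosine doublet
    a830, a850 = _solve_two_band(geo["tyr_830"], geo["tyr_850"],
                                 _W["tyr_buried"], _W["tyr_exposed"],
                                 tr("tyr_ratio"), 2.8 * K)
    fp += [("tyr_830", *geo["tyr_830"], a830), ("tyr_850", *geo["tyr_850"], a850)]
    # Amide I envelope
    a1655 = 1.0 * K
    area1655 = gaussian_area(a1655, geo["amide_1655"][1])
    q = tr("beta_alpha_amide1")
    area1670 = 0.45 * q * area1655
    area1685 = 0.55 * q * area1655
    fp += [
        ("amide_1617", *geo["amide_1617"], 0.25 * a1655),
        ("amide_1655", *geo["amide_1655"], a1655),
        ("amide_1670", *geo["amide_1670"],
         area1670 / gaussian_area(1.0, geo["amide_1670"][1])),
        ("amide_1685", *geo["amide_1685"],
         area1685 / gaussian_area(1.0, geo["amide_1685"][1])),
    ]
    # fixed fingerprint bands
    for name in _FP_FIXED:
        c, f = geo[name]
        fp.append((name, c, f, vol.fixed_amps[name] * K / 1000.0))

    # HWN: CH family, with the CH3 center following the folding trajectory
    hwn: List[Tuple[str, float, float, float]] = []
    for name in _HWN_CH:
        c, f = geo[name]
        if name == "ch3_sym_2930":
            c = tr("ch3_position")
        hwn.append((name, c, f, vol.fixed_amps[name] * K / 1000.0))
    # OH family: relative shape, 3458 from the bound-water ratio, overall
    # scale from the water mass % through the calibration inverse
    f3277 = geo["oh_strong_3277"][1]
    f3458 = geo["oh_weak_3458"][1]
    rel3458 = tr("bound_water_ratio") * (
        vol.fixed_amps["oh_strong_3277"] * f3277) / f3458
    oh_unit = []
    for name in _HWN_OH:
        c, f = geo[name]
        amp = rel3458 if name == "oh_weak_3458" else vol.fixed_amps[name]
        oh_unit.append((name, c, f, amp))
    r_target = calibration.to_ratio(float(vol.water_at(z_rel)))
    num_w, den_w = _W["water_oh"], _W["keratin_ch"]
    ch_cfa = [(c, f, a) for _, c, f, a in hwn]
    oh_cfa = [(c, f, a) for _, c, f, a in oh_unit]
    n_ch = sum_window_area(ch_cfa, num_w.lo, num_w.hi)
    d_ch = sum_window_area(ch_cfa, den_w.lo, den_w.hi)
    n_oh = sum_window_area(oh_cfa, num_w.lo, num_w.hi)
    d_oh = sum_window_area(oh_cfa, den_w.lo, den_w.hi)
    scale = (r_target * d_ch - n_ch) / (n_oh - r_target * d_oh)
    if scale <= 0:
        raise ValidationError("water trajectory not realisable (OH scale <= 0)")
    hwn += [(name, c, f, a * scale) for (name, c, f, a) in oh_unit]
    return fp, hwn


def _analytic_metrics(fp_params, hwn_params,
                      calibration: WaterCalibration) -> Dict[str, float]:
    """Exact metric values implied by a band-parameter set (erf integrals)."""
    fp = {name: (c, f, a) for name, c, f, a in fp_params}
    hw = {name: (c, f, a) for name, c, f, a in hwn_params}
    fp_cfa = list(fp.values())
    hw_cfa = list(hw.values())

    def win(params, w):
        return sum_window_area(params, w.lo, w.hi)

    area = lambda entry: gaussian_area(entry[2], entry[1])
    out = {
        "beta_alpha_cc": win(fp_cfa, _W["beta_cc"]) / win(fp_cfa, _W["alpha_cc"]),
        "ss_stability": win(fp_cfa, _W["ss_ggg"]) / win(fp_cfa, _W["ss_total"]),
        "cs_ss": win(fp_cfa, _W["cs_cys"]) / win(fp_cfa, _W["ss_total"]),
        "tyr_ratio": win(fp_cfa, _W["tyr_buried"]) / win(fp_cfa, _W["tyr_exposed"]),
        "beta_alpha_amide1":
            (area(fp["amide_1670"]) + area(fp["amide_1685"])) / area(fp["amide_1655"]),
        "ch3_position": hw["ch3_sym_2930"][0],
        "bound_water_ratio": area(hw["oh_weak_3458"]) / area(hw["oh_strong_3277"]),
    }
    r = win(hw_cfa, _W["water_oh"]) / win(hw_cfa, _W["keratin_ch"])
    out["water_mass_pct"] = calibration.to_mass_pct(r)
    return out


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def synth_spectrum(
    band_params,
    region: Region,
    grid: Optional[np.ndarray] = None,
    baseline: Optional[np.ndarray] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """One synthetic spectrum: sum of Gaussians + baseline + seeded noise.

    ``band_params`` is an iterable of ``(center, fwhm, amplitude)`` (an extra
    leading name element is tolerated).  Band centers must lie inside the
    grid.  The same seed reproduces the identical array.
    """
    region = Region(region)
    if grid is None:
        grid = FP_GRID if region is Region.FINGERPRINT else HWN_GRID
    params = [tuple(p[-3:]) for p in band_params]
    for c, f, a in params:
        if not (grid[0] <= c <= grid[-1]):
            raise ValidationError(f"band center {c:g} outside grid span")
    y = sum_of_gaussians(grid, params)
    if baseline is not None:
        y = y + np.asarray(baseline, dtype=float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=grid.size)
    return Spectrum(grid, y, region)


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery against the generator."""

    seed: int
    volunteers: List[VolunteerTruth]
    band_params: pd.DataFrame     # vol, depth_um, region, band, center, fwhm, amplitude
    metrics_depth: pd.DataFrame   # vol, depth_um, metric, value
    profiles: pd.DataFrame        # vol, metric, depth_pct, value
    calibration: WaterCalibration = field(default_factory=WaterCalibration)

    def volunteer(self, volunteer_id: str) -> VolunteerTruth:
        for v in self.volunteers:
            if v.volunteer_id == volunteer_id:
                return v
        raise KeyError(volunteer_id)

    def profile(self, volunteer_id: str, metric: str) -> np.ndarray:
        df = self.profiles
        sel = df[(df.volunteer == volunteer_id) & (df.metric == metric)]
        return sel.sort_values("depth_pct")["value"].to_numpy()

    def cohort_mean_profile(self, metric: str) -> np.ndarray:
        df = self.profiles[self.profiles.metric == metric]
        return (df.groupby("depth_pct")["value"].mean()
                .sort_index().to_numpy())


def _draw_volunteer(rng: np.random.Generator, idx: int, profile: ProfileSpec,
                    noise: NoiseSpec) -> VolunteerTruth:
    vid = f"v{idx:02d}"
    t = rng.uniform(*noise.thickness_range_um)
    surf = rng.uniform(*noise.surface_range_um)
    k = 1000.0 * (1.0 + 0.05 * rng.standard_normal())
    cv = noise.volunteer_cv
    traj = {}
    for name, base in profile.trajectories.items():
        if name == "ch3_position":
            traj[name] = base + rng.normal(0.0, 5.0 * cv)
        else:
            mult = float(np.clip(1.0 + cv * rng.standard_normal(), 0.85, 1.15))
            traj[name] = base * mult
    traj["ss_stability"] = np.clip(traj["ss_stability"], 0.02, 0.98)
    water = replace(
        profile.water,
        surface_pct=float(np.clip(profile.water.surface_pct + rng.normal(0, 1.0),
                                  12.0, 18.0)),
        boundary_pct=float(np.clip(profile.water.boundary_pct + rng.normal(0, 1.5),
                                   35.0, 45.0)),
    )
    geometry: Dict[str, Tuple[float, float]] = {}
    for name, (c, f) in _FP_METRIC_GEOM.items():
        dc = float(np.clip(rng.normal(0.0, 0.8), -2.0, 2.0))
        df_ = float(np.clip(rng.normal(0.0, 1.0), -3.0, 3.0))
        geometry[name] = (c + dc, f + df_)
    for name, (c, f, _) in _FP_FIXED.items():
        geometry[name] = (c + float(np.clip(rng.normal(0, 0.5), -1.5, 1.5)), f)
    for name, (c, f, _) in _HWN_CH.items():
        dc = float(np.clip(rng.normal(0.0, 0.6), -1.5, 1.5))
        df_ = float(np.clip(rng.normal(0.0, 1.0), -3.0, 3.0))
        geometry[name] = (c + dc, f + df_)
    for name, (c, f, _) in _HWN_OH.items():
        dc = float(np.clip(rng.normal(0.0, 2.0), -5.0, 5.0))
        df_ = float(np.clip(rng.normal(0.0, 3.0), -8.0, 8.0))
        geometry[name] = (c + dc, f + df_)
    amps: Dict[str, float] = {}
    for table in (_FP_FIXED, _HWN_CH):
        for name, (_, _, a) in table.items():
            amps[name] = a * (1.0 + 0.1 * rng.standard_normal())
    for name, (_, _, a) in _HWN_OH.items():
        if a is not None:
            amps[name] = a * (1.0 + (0.1 * rng.standard_normal()
                                     if name != "oh_strong_3277" else 0.0))
    return VolunteerTruth(vid, surf, t, k, traj, water, geometry, amps)


def synth_cohort(
    profile_spec: Optional[ProfileSpec] = None,
    noise_spec: Optional[NoiseSpec] = None,
    n_volunteers: int = 11,
    n_positions: int = 10,
    seed: int = 1,
    depths_um: Optional[np.ndarray] = None,
    calibration: Optional[WaterCalibration] = None,
) -> Tuple[Cohort, SyntheticGroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Defaults mirror the study design: 11 volunteers, 10 positions each,
    depths 0-40 um in 2 um steps, both spectral regions.  Identical seeds
    reproduce the cohort bit-exactly.
    """
    if n_volunteers < 1 or n_positions < 1:
        raise ValidationError("need >= 1 volunteer and >= 1 position")
    profile = profile_spec or ProfileSpec()
    noise = noise_spec or NoiseSpec()
    cal = calibration or WaterCalibration()
    depths = np.arange(0.0, 40.0 + 1.0, 2.0) if depths_um is None \
        else np.asarray(depths_um, dtype=float)
    rng = np.random.default_rng(seed)

    volunteers: List[VolunteerRecord] = []
    truths: List[VolunteerTruth] = []
    bp_rows, md_rows, pr_rows = [], [], []

    for vi in range(n_volunteers):
        vol = _draw_volunteer(rng, vi, profile, noise)
        truths.append(vol)
        width = noise.transition_width_um
        atten = 1.0 / (1.0 + np.exp(-(depths - vol.surface_um) / width))

        # true band parameters and metrics per acquisition depth
        per_depth = []
        depth_metrics: Dict[str, List[float]] = {m: [] for m in METRIC_NAMES}
        for z, att in zip(depths, atten):
            z_rel = z - vol.surface_um
            pct = 100.0 * max(z_rel, 0.0) / vol.thickness_um
            fp_p, hwn_p = _band_params_at(vol, pct, z_rel, cal)
            per_depth.append((fp_p, hwn_p, att))
            for region, params in (("fingerprint", fp_p), ("hwn", hwn_p)):
                for name, c, f, a in params:
                    bp_rows.append((vol.volunteer_id, z, region, name, c, f, a))
            for metric, value in _analytic_metrics(fp_p, hwn_p, cal).items():
                md_rows.append((vol.volunteer_id, z, metric, value))
                depth_metrics[metric].append(value)

        # truth profiles on the normalised grid: the true per-depth metric
        # values resampled with the true geometry -- i.e. the best recovery
        # any analysis of the 2 um-sampled data could achieve.  Continuous
        # trajectory values remain available via VolunteerTruth.metric_at.
        from .depth import normalize_and_resample

        for metric in METRIC_NAMES:
            _, resampled = normalize_and_resample(
                depths, np.array(depth_metrics[metric]),
                vol.surface_um, vol.thickness_um)
            for pct, value in zip(TRAJ_GRID, resampled):
                pr_rows.append((vol.volunteer_id, metric, float(pct), value))

        series = []
        for pi in range(n_positions):
            pos_scale = float(np.exp(noise.position_scale_sigma
                                     * rng.standard_normal()))
            fp_list, hwn_list = [], []
            for (fp_p, hwn_p, att) in per_depth:
                b0 = rng.uniform(*noise.baseline_offset)
                b1 = rng.uniform(*noise.baseline_slope)
                fl = rng.uniform(*noise.fluorescence_amplitude)
                base_fp = (b0 + b1 * (FP_GRID - 1100.0)
                           + gaussian(FP_GRID, noise.fluorescence_center,
                                      noise.fluorescence_fwhm, fl))
                y_fp = sum_of_gaussians(
                    FP_GRID,
                    [(c, f, a * att * pos_scale) for _, c, f, a in fp_p]
                ) + base_fp
                if noise.sigma_fp > 0:
                    y_fp = y_fp + rng.normal(
                        0.0, noise.sigma_fp * vol.k_scale * pos_scale,
                        size=FP_GRID.size)
                fp_list.append(Spectrum(FP_GRID, y_fp, Region.FINGERPRINT))

                d0 = rng.uniform(*noise.hwn_hinge_offset)
                d1 = rng.uniform(*noise.hwn_hinge_slopes)
                d2 = rng.uniform(*noise.hwn_hinge_slopes)
                base_hwn = (d0 + d1 * (HWN_GRID - 3300.0)
                            + d2 * np.maximum(0.0, HWN_GRID - 3100.0))
                y_hwn = sum_of_gaussians(
                    HWN_GRID,
                    [(c, f, a * att * pos_scale) for _, c, f, a in hwn_p]
                ) + base_hwn
                if noise.sigma_hwn > 0:
                    y_hwn = y_hwn + rng.normal(
                        0.0, noise.sigma_hwn * vol.k_scale * pos_scale,
                        size=HWN_GRID.size)
                hwn_list.append(Spectrum(HWN_GRID, y_hwn, Region.HWN))
            series.append(DepthSeries(depths, fp_list, hwn_list,
                                      position_id=f"p{pi:02d}",
                                      volunteer_id=vol.volunteer_id))
        volunteers.append(VolunteerRecord(vol.volunteer_id, series))

    cohort = Cohort(volunteers, metadata={
        "seed": int(seed), "n_volunteers": n_volunteers,
        "n_positions": n_positions, "synthetic": True,
    })
    truth = SyntheticGroundTruth(
        seed=int(seed),
        volunteers=truths,
        band_params=pd.DataFrame(
            bp_rows, columns=["volunteer", "depth_um", "region", "band",
                              "center", "fwhm", "amplitude"]),
        metrics_depth=pd.DataFrame(
            md_rows, columns=["volunteer", "depth_um", "metric", "value"]),
        profiles=pd.DataFrame(
            pr_rows, columns=["volunteer", "metric", "depth_pct", "value"]),
        calibration=cal,
    )
    return cohort, truth
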