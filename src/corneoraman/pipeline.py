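"""End-to-end depth-profile analysis: preprocess -> fit -> metrics -> stats.

The central objects follow the statsmodels convention:

>>> model = CohortDepthModel(cohort, RunConfig(seed=1))
>>> results = model.fit()
>>> results.cohort_mean()          # mean +/- SD metric profiles, % SC grid
>>> results.adjacent_depth_stats() # paired t between neighbouring depths
>>> print(results.summary())

Per volunteer the pipeline (i) PCA-denoises the fingerprint spectra depth by
depth across lateral positions, (ii) locates the skin surface per position
from the baseline-corrected 1655 cm-1 profile and averages the estimates,
(iii) computes the eight indicators per spectrum (anchor baselines + AUC
windows; constrained Amide I and HWN deconvolutions), (iv) averages the
positions, estimates SC thickness from the volunteer's water profile and
(v) resamples every metric onto the 0-100% SC grid in 10% steps.  Profiles
are stored surface -> depth; statistical traversal runs from the deepest
layers towards the surface, the direction of corneocyte maturation.

Everything is deterministic for a fixed config seed; per-spectrum fit seeds
are derived from it.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .deconv import ConstrainedBandModel, amide1_model, hwn_model
from .depth import find_surface, normalize_and_resample, percent_grid, sc_thickness
from .exceptions import CorneoramanError, FitError, ValidationError
from .metrics import (METRIC_NAMES, MetricVector, WaterCalibration, beta_alpha_cc,
                      cs_ss, ss_stability, tyr_ratio, water_mass_pct)
from .preprocess import (AnchorScheme, default_anchor_scheme, hwn_baseline,
                         pca_reconstruct, remove_linear_baseline)
from .spectra import Cohort, read_cohort, write_profiles
from .stats import jarque_bera, paired_t
from .windows import WindowRegistry, default_windows

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "CohortDepthModel", "CohortDepthResults", "run_analysis"]


@dataclass
class RunConfig:
    """Serializable settings of one analysis run."""

    seed: int = 0
    cohort_path: Optional[str] = None
    output_path: Optional[str] = None
    pca_components: int = 4
    n_fit_starts: int = 8
    early_stop: bool = True
    calibration_c: float = 1.0
    thickness_threshold: float = 0.5
    thickness_convention: str = "percent_per_um"
    smooth_window: int = 3
    grid_step_pct: float = 10.0
    extra_oh_centers: Tuple[float, float, float] = (3180.0, 3550.0, 3630.0)
    windows: Optional[Dict[str, Tuple[float, float]]] = None
    anchors: Optional[Dict] = None

    def window_registry(self) -> WindowRegistry:
        if self.windows is None:
            return default_windows()
        from .spectra import BandWindow

        return WindowRegistry([BandWindow(n, lo, hi)
                               for n, (lo, hi) in self.windows.items()])

    def anchor_scheme(self) -> AnchorScheme:
        if self.anchors is None:
            return default_anchor_scheme()
        from .preprocess import AnchorGroup

        groups = {
            k: AnchorGroup(tuple(v["band"]), tuple(v["lower"]), tuple(v["upper"]))
            for k, v in self.anchors.items()
        }
        return AnchorScheme(groups)

    def calibration(self) -> WaterCalibration:
        return WaterCalibration(self.calibration_c)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["extra_oh_centers"] = list(self.extra_oh_centers)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if "extra_oh_centers" in payload:
            payload["extra_oh_centers"] = tuple(payload["extra_oh_centers"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _fit_seed(base: int, vol_idx: int, pos_idx: int, depth_idx: int, region: int) -> int:
    return (base * 1_000_003 + vol_idx * 65_537 + pos_idx * 1_021
            + depth_idx * 17 + region) % (2 ** 31 - 1)


@dataclass
class CohortDepthResults:
    """Fitted depth-profile results for a whole cohort."""

    config: RunConfig
    metric_table: pd.DataFrame      # volunteer, position, depth_um, metric, value
    profiles: pd.DataFrame          # metric, volunteer, depth_pct, value
    geometry: pd.DataFrame          # volunteer, surface_um, thickness_um
    fit_diagnostics: pd.DataFrame   # per-fit convergence bookkeeping
    grid_pct: np.ndarray

    def cohort_mean(self) -> pd.DataFrame:
        """Mean +/- SD over volunteers per metric and % SC depth."""
        g = self.profiles.groupby(["metric", "depth_pct"])["value"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        return out

    def volunteer_profile(self, volunteer_id: str, metric: str) -> np.ndarray:
        df = self.profiles
        sel = df[(df.volunteer == volunteer_id) & (df.metric == metric)]
        return sel.sort_values("depth_pct")["value"].to_numpy()

    def cohort_mean_profile(self, metric: str) -> np.ndarray:
        df = self.profiles[self.profiles.metric == metric]
        return df.groupby("depth_pct")["value"].mean().sort_index().to_numpy()

    def adjacent_depth_stats(self) -> pd.DataFrame:
        """Paired t-tests between neighbouring depths, deepest -> surface.

        One row per metric and depth pair (e.g. 100% vs 90%), with the
        Jarque-Bera normality check of the paired differences.  p-values are
        reported raw (no multiple-testing correction).
        """
        rows = []
        grid = sorted(self.profiles.depth_pct.unique(), reverse=True)
        for metric in self.profiles.metric.unique():
            sub = self.profiles[self.profiles.metric == metric]
            wide = sub.pivot(index="volunteer", columns="depth_pct", values="value")
            for deep, shallow in zip(grid[:-1], grid[1:]):
                a = wide[deep].to_numpy()
                b = wide[shallow].to_numpy()
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < 3:
                    continue
                res = paired_t(a[ok], b[ok])
                try:
                    jb = jarque_bera(a[ok] - b[ok])
                    jb_p = jb.p
                except (ValidationError, CorneoramanError):
                    jb_p = float("nan")
                rows.append({
                    "metric": metric, "depth_a_pct": deep, "depth_b_pct": shallow,
                    "t": res.statistic, "p": res.p, "grade": res.grade,
                    "n": res.n, "jb_p": jb_p,
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        mean = self.cohort_mean()
        n_vol = self.profiles.volunteer.nunique()
        lines = [
            "Stratum corneum depth-profile analysis",
            f"  volunteers : {n_vol}",
            f"  thickness  : {self.geometry.thickness_um.mean():.1f} +/- "
            f"{self.geometry.thickness_um.std():.1f} um",
            f"  metrics    : {', '.join(METRIC_NAMES)}",
            "",
            "  cohort means at the surface (0%), mid-SC (50%) and boundary (100%):",
        ]
        for metric in METRIC_NAMES:
            row = {p: mean[(mean.metric == metric) & (mean.depth_pct == p)]
                   for p in (0.0, 50.0, 100.0)}
            vals = []
            for p in (0.0, 50.0, 100.0):
                r = row[p]
                vals.append(f"{float(r['mean'].iloc[0]):.4g}" if len(r) else "--")
            lines.append(f"    {metric:<20} {vals[0]:>10} {vals[1]:>10} {vals[2]:>10}")
        return "\n".join(lines)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metric_table.to_csv(out / "metrics_per_spectrum.tsv", sep="\t",
                                 index=False, float_format="%.12g")
        write_profiles(self.profiles, out / "profiles.tsv")
        self.cohort_mean().to_csv(out / "cohort_mean_profiles.tsv", sep="\t",
                                  index=False, float_format="%.12g")
        self.geometry.to_csv(out / "geometry.tsv", sep="\t", index=False,
                             float_format="%.12g")
        stats = self.adjacent_depth_stats()
        stats.to_csv(out / "stats_report.tsv", sep="\t", index=False,
                     float_format="%.12g")
        self.config.to_yaml(out / "run_config.yaml")
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")
        return out


class CohortDepthModel:
    """Depth-profile model of keratin conformation and hydration for a cohort."""

    def __init__(self, cohort: Cohort, config: Optional[RunConfig] = None):
        self.cohort = cohort
        self.config = config or RunConfig()

    # -- per-spectrum computations ----------------------------------------

    def _fp_metrics(self, fp_spectrum, anchors, windows, amide_cs, seed,
                    warm) -> Tuple[Dict[str, float], object, float]:
        """Fingerprint metrics + amide fit results + surface profile sample."""
        cfg = self.config
        vals: Dict[str, float] = {}
        vals["beta_alpha_cc"] = beta_alpha_cc(fp_spectrum, anchors, windows)
        vals["ss_stability"] = ss_stability(fp_spectrum, anchors, windows)
        vals["cs_ss"] = cs_ss(fp_spectrum, anchors, windows)
        vals["tyr_ratio"] = tyr_ratio(fp_spectrum, anchors, windows)
        segment = remove_linear_baseline(fp_spectrum, anchors["amide1"])
        i1655 = segment.intensity_at(1655.0)
        fit = ConstrainedBandModel(segment, amide_cs).fit(
            seed=seed, n_starts=cfg.n_fit_starts, early_stop=cfg.early_stop,
            warm_start=warm)
        vals["beta_alpha_amide1"] = fit.amide1_ratio()
        return vals, fit, i1655

    def _hwn_metrics(self, hwn_spectrum, windows, hwn_cs, calibration, seed,
                     warm) -> Tuple[Dict[str, float], object]:
        cfg = self.config
        corrected = hwn_baseline(hwn_spectrum)
        vals = {"water_mass_pct": water_mass_pct(corrected, calibration, windows)}
        fit = ConstrainedBandModel(corrected, hwn_cs).fit(
            seed=seed, n_starts=cfg.n_fit_starts, early_stop=cfg.early_stop,
            warm_start=warm)
        vals["ch3_position"] = fit.ch3_peak_position()
        vals["bound_water_ratio"] = fit.bound_water_ratio()
        return vals, fit

    # -- main entry point --------------------------------------------------

    def fit(self) -> CohortDepthResults:
        cfg = self.config
        anchors = cfg.anchor_scheme()
        windows = cfg.window_registry()
        amide_cs = amide1_model()
        hwn_cs = hwn_model(cfg.extra_oh_centers)
        calibration = cfg.calibration()
        grid = percent_grid(cfg.grid_step_pct)

        metric_rows, geom_rows, diag_rows, profile_rows = [], [], [], []

        for vi, vol in enumerate(self.cohort.volunteers):
            t0 = time.perf_counter()
            depths = vol.series[0].depths_um
            n_depths = depths.size
            n_pos = len(vol.series)
            for ds in vol.series:
                if ds.depths_um.size != n_depths or not np.allclose(
                        ds.depths_um, depths):
                    raise ValidationError(
                        f"volunteer {vol.volunteer_id}: depth grids differ "
                        f"between positions")

            # PCA across positions, depth by depth (fingerprint only)
            fp_matrix: List[List] = [list(ds.spectra_fp) for ds in vol.series]
            if n_pos >= cfg.pca_components and cfg.pca_components > 0:
                for di in range(n_depths):
                    group = [fp_matrix[pi][di] for pi in range(n_pos)]
                    recon = pca_reconstruct(group, k=cfg.pca_components)
                    for pi in range(n_pos):
                        fp_matrix[pi][di] = recon[pi]
            else:
                log.info("volunteer %s: %d positions < %d PCs, PCA skipped",
                         vol.volunteer_id, n_pos, cfg.pca_components)

            # per position, per depth: metrics + the 1655 cm-1 surface profile
            per_pos_values = np.full((n_pos, n_depths, len(METRIC_NAMES)), np.nan)
            surfaces = []
            for pi, ds in enumerate(vol.series):
                i1655_profile = np.zeros(n_depths)
                warm_fp = warm_hwn = None
                for di in range(n_depths):
                    stage = (vol.volunteer_id, ds.position_id, float(depths[di]))
                    try:
                        fp_vals, fp_fit, i1655 = self._fp_metrics(
                            fp_matrix[pi][di], anchors, windows, amide_cs,
                            _fit_seed(cfg.seed, vi, pi, di, 0), warm_fp)
                        hwn_vals, hwn_fit = self._hwn_metrics(
                            ds.spectra_hwn[di], windows, hwn_cs, calibration,
                            _fit_seed(cfg.seed, vi, pi, di, 1), warm_hwn)
                    except CorneoramanError as exc:
                        raise FitError(
                            f"stage failure at volunteer={stage[0]} "
                            f"position={stage[1]} depth={stage[2]:g} um: {exc}"
                        ) from exc
                    i1655_profile[di] = i1655
                    warm_fp = list(fp_fit.bands.values())
                    warm_hwn = list(hwn_fit.bands.values())
                    vals = {**fp_vals, **hwn_vals}
                    for mi, name in enumerate(METRIC_NAMES):
                        per_pos_values[pi, di, mi] = vals[name]
                        metric_rows.append((vol.volunteer_id, ds.position_id,
                                            float(depths[di]), name, vals[name]))
                    diag_rows.append((vol.volunteer_id, ds.position_id,
                                      float(depths[di]), fp_fit.converged,
                                      hwn_fit.converged, fp_fit.n_starts_used,
                                      hwn_fit.n_starts_used))
                surfaces.append(find_surface(depths, i1655_profile).surface_um)

            surface = float(np.mean(surfaces))
            # depths more than one increment above the surface hold no tissue
            # signal; their ratio metrics are noise quotients and are masked.
            # The sample straddling the surface is kept: the 0% SC grid point
            # interpolates between it and the first sample inside the skin.
            step = float(np.median(np.diff(depths)))
            air = depths < surface - step
            per_pos_values[:, air, :] = np.nan
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vol_values = np.nanmean(per_pos_values, axis=0)  # (depths, metrics)

            water_idx = METRIC_NAMES.index("water_mass_pct")
            aligned = depths - surface
            inward = aligned >= -1e-9
            thickness, _ = sc_thickness(
                aligned[inward], vol_values[inward, water_idx],
                threshold=cfg.thickness_threshold,
                smooth_window=cfg.smooth_window,
                convention=cfg.thickness_convention)
            geom_rows.append((vol.volunteer_id, surface, thickness))

            for mi, name in enumerate(METRIC_NAMES):
                _, resampled = normalize_and_resample(
                    depths, vol_values[:, mi], surface, thickness,
                    cfg.grid_step_pct)
                for p, v in zip(grid, resampled):
                    profile_rows.append((name, vol.volunteer_id, float(p), v))
            log.info("volunteer %s done in %.1f s", vol.volunteer_id,
                     time.perf_counter() - t0)

        return CohortDepthResults(
            config=cfg,
            metric_table=pd.DataFrame(
                metric_rows,
                columns=["volunteer", "position", "depth_um", "metric", "value"]),
            profiles=pd.DataFrame(
                profile_rows,
                columns=["metric", "volunteer", "depth_pct", "value"]),
            geometry=pd.DataFrame(
                geom_rows, columns=["volunteer", "surface_um", "thickness_um"]),
            fit_diagnostics=pd.DataFrame(
                diag_rows,
                columns=["volunteer", "position", "depth_um", "fp_converged",
                         "hwn_converged", "fp_starts", "hwn_starts"]),
            grid_pct=grid,
        )


def run_analysis(config: RunConfig) -> Path:
    """Load the cohort named in ``config``, fit, and write all outputs."""
    if config.cohort_path is None or config.output_path is None:
        raise ValidationError("config must set cohort_path and output_path")
    cohort = read_cohort(config.cohort_path)
    results = CohortDepthModel(cohort, config).fit()
    return results.save(config.output_path)
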