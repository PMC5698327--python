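"""Domain types for depth-resolved Raman spectra and their on-disk layout.

A measurement campaign produces, for every volunteer and lateral skin
position, a stack of spectra acquired at fixed depth increments (default
2 um from 0 to 40 um), each depth yielding one fingerprint spectrum
(400-2000 cm-1) and one high-wavenumber (HWN, 2000-4000 cm-1) spectrum.

On disk a cohort is laid out as::

    cohort_root/
      manifest.yaml                 # volunteers, positions, depth step
      <volunteer>/<position>/fingerprint.tsv
      <volunteer>/<position>/hwn.tsv

Each TSV holds a ``wavenumber`` column plus one intensity column per depth
(named ``d<depth-in-um>``); '#'-prefixed comment lines carry metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import MissingDataError, ValidationError
from ._gaussian import gaussian_area

__all__ = [
    "Region",
    "Spectrum",
    "BandWindow",
    "GaussianBand",
    "BandConstraint",
    "ConstraintSet",
    "DepthSeries",
    "VolunteerRecord",
    "Cohort",
    "read_depth_series",
    "write_depth_series",
    "read_cohort",
    "write_cohort",
    "write_profiles",
    "read_profiles",
]


class Region(str, Enum):
    """Spectral region tag."""

    FINGERPRINT = "fingerprint"
    HWN = "hwn"


@dataclass(frozen=True)
class Spectrum:
    """One wavenumber-indexed intensity trace.

    Parameters
    ----------
    wavenumbers : array-like of cm-1 values, strictly increasing, length >= 16.
    intensities : array-like of detector counts, same length.
    region : which spectral region the trace belongs to.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    region: Region

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", i)
        object.__setattr__(self, "region", Region(self.region))
        if w.ndim != 1 or i.ndim != 1:
            raise ValidationError("wavenumbers and intensities must be 1-D")
        if w.size != i.size:
            raise ValidationError(
                f"length mismatch: {w.size} wavenumbers vs {i.size} intensities"
            )
        if w.size < 16:
            raise ValidationError(f"spectrum too short ({w.size} points, need >= 16)")
        dw = np.diff(w)
        if np.any(dw <= 0):
            bad = w[1:][dw <= 0][0]
            raise ValidationError(
                f"wavenumbers not strictly increasing (offending value {bad:g} cm-1)"
            )
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(i))):
            raise ValidationError("non-finite values in spectrum")

    @property
    def span(self) -> Tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def intensity_at(self, wavenumber: float) -> float:
        """Linearly interpolated intensity at ``wavenumber``."""
        lo, hi = self.span
        if not (lo <= wavenumber <= hi):
            raise ValidationError(
                f"wavenumber {wavenumber:g} outside spectrum span [{lo:g}, {hi:g}]"
            )
        return float(np.interp(wavenumber, self.wavenumbers, self.intensities))

    def with_intensities(self, intensities) -> "Spectrum":
        return Spectrum(self.wavenumbers, np.asarray(intensities, float), self.region)

    def scaled(self, factor: float) -> "Spectrum":
        return self.with_intensities(self.intensities * factor)


@dataclass(frozen=True)
class BandWindow:
    """A named integration window ``[lo, hi]`` in cm-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(
                f"window {self.name!r}: lo ({self.lo:g}) must be < hi ({self.hi:g})"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class GaussianBand:
    """A parametric Gaussian band (center, FWHM, amplitude)."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValidationError(f"FWHM must be > 0, got {self.fwhm:g}")
        if self.amplitude < 0:
            raise ValidationError(f"amplitude must be >= 0, got {self.amplitude:g}")

    @property
    def area(self) -> float:
        """Closed-form area under the Gaussian curve (AUGC)."""
        return gaussian_area(self.amplitude, self.fwhm)


@dataclass(frozen=True)
class BandConstraint:
    """Fitting box for one band: nominal value +/- slack per parameter."""

    name: str
    center: float
    center_slack: float
    fwhm: float
    fwhm_slack: float

    def __post_init__(self):
        if self.center_slack < 0 or self.fwhm_slack < 0:
            raise ValidationError(f"band {self.name!r}: slacks must be >= 0")
        if self.fwhm - self.fwhm_slack <= 0:
            raise ValidationError(
                f"band {self.name!r}: FWHM box must stay positive"
            )


@dataclass(frozen=True)
class ConstraintSet:
    """An ordered set of band constraint boxes plus the fit range."""

    bands: Tuple[BandConstraint, ...]
    fit_range: Tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        lo, hi = self.fit_range
        if not lo < hi:
            raise ValidationError("fit_range lo must be < hi")
        centers = [b.center for b in self.bands]
        if len(set(centers)) != len(centers):
            raise ValidationError("constraint boxes must have distinct nominal centers")

    def __len__(self) -> int:
        return len(self.bands)

    def names(self) -> List[str]:
        return [b.name for b in self.bands]

    def band(self, name: str) -> BandConstraint:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


def _check_depths(depths: np.ndarray, step: Optional[float]) -> float:
    if depths.ndim != 1 or depths.size < 2:
        raise ValidationError("need at least two depths")
    if np.any(depths < 0):
        raise ValidationError("depths must be non-negative")
    d = np.diff(depths)
    if np.any(d <= 0):
        raise ValidationError("depths must be strictly increasing")
    if not np.allclose(d, d[0], rtol=0, atol=1e-9):
        raise ValidationError("depth increment must be constant")
    if step is not None and not np.isclose(d[0], step, rtol=0, atol=1e-9):
        raise ValidationError(
            f"depth increment {d[0]:g} um does not match configured step {step:g} um"
        )
    return float(d[0])


@dataclass
class DepthSeries:
    """Ordered stack of paired fingerprint/HWN spectra at known depths."""

    depths_um: np.ndarray
    spectra_fp: List[Spectrum]
    spectra_hwn: List[Spectrum]
    position_id: str = "p00"
    volunteer_id: str = "v00"
    step_um: Optional[float] = None

    def __post_init__(self):
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.step_um = _check_depths(self.depths_um, self.step_um)
        n = self.depths_um.size
        if len(self.spectra_fp) != n or len(self.spectra_hwn) != n:
            raise ValidationError(
                f"need one fingerprint and one hwn spectrum per depth "
                f"({n} depths, {len(self.spectra_fp)} fp, {len(self.spectra_hwn)} hwn)"
            )
        for s in self.spectra_fp:
            if s.region is not Region.FINGERPRINT:
                raise ValidationError("spectra_fp must all be fingerprint spectra")
        for s in self.spectra_hwn:
            if s.region is not Region.HWN:
                raise ValidationError("spectra_hwn must all be hwn spectra")

    @property
    def n_depths(self) -> int:
        return int(self.depths_um.size)

    def intensity_profile(self, wavenumber: float, region: Region = Region.FINGERPRINT):
        """Intensity at a fixed wavenumber as a function of depth."""
        spectra = self.spectra_fp if Region(region) is Region.FINGERPRINT else self.spectra_hwn
        return np.array([s.intensity_at(wavenumber) for s in spectra])


@dataclass
class VolunteerRecord:
    volunteer_id: str
    series: List[DepthSeries] = field(default_factory=list)

    def __post_init__(self):
        if not self.series:
            raise ValidationError(f"volunteer {self.volunteer_id}: needs >= 1 DepthSeries")


@dataclass
class Cohort:
    """All volunteers of one study, sharing grids and the depth step."""

    volunteers: List[VolunteerRecord]
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.volunteers:
            raise ValidationError("cohort must contain at least one volunteer")
        ref = self.volunteers[0].series[0]
        for vol in self.volunteers:
            for ds in vol.series:
                if not np.isclose(ds.step_um, ref.step_um):
                    raise ValidationError("all DepthSeries must share the depth increment")
                for a, b in ((ds.spectra_fp[0], ref.spectra_fp[0]),
                             (ds.spectra_hwn[0], ref.spectra_hwn[0])):
                    if a.wavenumbers.size != b.wavenumbers.size or not np.allclose(
                        a.wavenumbers, b.wavenumbers
                    ):
                        raise ValidationError(
                            "all DepthSeries must share the wavenumber grid per region"
                        )

    @property
    def depth_step_um(self) -> float:
        return self.volunteers[0].series[0].step_um

    def volunteer_ids(self) -> List[str]:
        return [v.volunteer_id for v in self.volunteers]


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

_REGION_FILES = {Region.FINGERPRINT: "fingerprint.tsv", Region.HWN: "hwn.tsv"}


def _depth_col(depth: float) -> str:
    return f"d{depth:g}"


def _write_region_tsv(path: Path, depths: np.ndarray, spectra: List[Spectrum],
                      region: Region, position_id: str, volunteer_id: str) -> None:
    grid = spectra[0].wavenumbers
    data = {"wavenumber": grid}
    for depth, spec in zip(depths, spectra):
        data[_depth_col(depth)] = spec.intensities
    df = pd.DataFrame(data)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# region: {region.value}\n")
        fh.write(f"# volunteer: {volunteer_id}\n")
        fh.write(f"# position: {position_id}\n")
        fh.write("# depths_um: " + " ".join(f"{d:g}" for d in depths) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def _read_region_tsv(path: Path, region: Region) -> Tuple[np.ndarray, List[Spectrum], dict]:
    if not path.is_file():
        raise MissingDataError(f"missing {region.value} file: {path}")
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if "wavenumber" not in df.columns:
        raise ValidationError(f"{path}: missing 'wavenumber' column")
    depth_cols = [c for c in df.columns if c.startswith("d")]
    if not depth_cols:
        raise MissingDataError(f"{path}: no depth columns found")
    depths = np.array([float(c[1:]) for c in depth_cols])
    order = np.argsort(depths)
    depths = depths[order]
    grid = df["wavenumber"].to_numpy(float)
    spectra = []
    for idx in order:
        col = depth_cols[idx]
        spectra.append(Spectrum(grid, df[col].to_numpy(float), region))
    return depths, spectra, meta


def write_depth_series(series: DepthSeries, path) -> Path:
    """Write one position directory (both region TSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_region_tsv(path / _REGION_FILES[Region.FINGERPRINT], series.depths_um,
                      series.spectra_fp, Region.FINGERPRINT,
                      series.position_id, series.volunteer_id)
    _write_region_tsv(path / _REGION_FILES[Region.HWN], series.depths_um,
                      series.spectra_hwn, Region.HWN,
                      series.position_id, series.volunteer_id)
    return path


def read_depth_series(path, step_um: Optional[float] = None) -> DepthSeries:
    """Read one position directory into a validated :class:`DepthSeries`."""
    path = Path(path)
    if not path.is_dir():
        raise MissingDataError(f"no such position directory: {path}")
    if not any(path.iterdir()):
        raise MissingDataError(f"no depth files found in {path}")
    depths_fp, fp, meta = _read_region_tsv(path / _REGION_FILES[Region.FINGERPRINT],
                                           Region.FINGERPRINT)
    depths_hwn, hwn, _ = _read_region_tsv(path / _REGION_FILES[Region.HWN], Region.HWN)
    if depths_fp.size != depths_hwn.size or not np.allclose(depths_fp, depths_hwn):
        raise ValidationError(
            f"{path}: fingerprint and hwn files disagree on the depth grid"
        )
    return DepthSeries(
        depths_fp, fp, hwn,
        position_id=meta.get("position", path.name),
        volunteer_id=meta.get("volunteer", path.parent.name),
        step_um=step_um,
    )


def write_cohort(cohort: Cohort, root) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "depth_step_um": float(cohort.depth_step_um),
        "volunteers": {},
        "metadata": {k: v for k, v in cohort.metadata.items()
                     if isinstance(v, (str, int, float, bool, list))},
    }
    for vol in cohort.volunteers:
        manifest["volunteers"][vol.volunteer_id] = [ds.position_id for ds in vol.series]
        for ds in vol.series:
            write_depth_series(ds, root / vol.volunteer_id / ds.position_id)
    with open(root / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return root


def read_cohort(root) -> Cohort:
    root = Path(root)
    manifest_path = root / "manifest.yaml"
    if not manifest_path.is_file():
        raise MissingDataError(f"no manifest.yaml in {root}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    step = float(manifest.get("depth_step_um", 2.0))
    volunteers = []
    for vid, positions in manifest["volunteers"].items():
        series = [read_depth_series(root / vid / pid, step_um=step) for pid in positions]
        volunteers.append(VolunteerRecord(vid, series))
    return Cohort(volunteers, metadata=manifest.get("metadata", {}) or {})


# ---------------------------------------------------------------------------
# metric-profile tables
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["metric", "volunteer", "depth_pct", "value"]


def write_profiles(table: pd.DataFrame, path) -> Path:
    """Write a metric-profile table (metric, volunteer, depth_pct, value) as TSV.

    Values round-trip losslessly at 12 significant digits.
    """
    missing = [c for c in PROFILE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"profile table missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[PROFILE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_profiles(path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise MissingDataError(f"no profile table at {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("depth_pct", "value"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df
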