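"""Synthetic cohort generator: determinism, counts, truth consistency."""

import numpy as np
import pytest

from corneoraman import (NoiseSpec, ProfileSpec, Region, ValidationError,
                         synth_cohort, synth_spectrum)
from corneoraman.metrics import METRIC_NAMES
from corneoraman.synth import (FP_GRID, TRAJ_GRID, _analytic_metrics,
                               _band_params_at)


class TestSynthSpectrum:
    def test_zero_bands_zero_noise_gives_zero_spectrum(self):
        s = synth_spectrum([], Region.FINGERPRINT)
        assert np.all(s.intensities == 0.0)

    def test_single_gaussian_peaks_at_grid_point_nearest_center(self):
        s = synth_spectrum([(700.3, 10.0, 2.0)], Region.FINGERPRINT)
        i = np.argmax(s.intensities)
        assert s.wavenumbers[i] == pytest.approx(700.0)
        assert s.intensities[i] == pytest.approx(
            2.0 * np.exp(-0.5 * (0.3 / (10.0 / 2.3548200450309493)) ** 2),
            rel=1e-6)

    def test_same_seed_reproduces_identical_arrays(self):
        a = synth_spectrum([(700.0, 10.0, 1.0)], Region.FINGERPRINT,
                           noise_sigma=0.1, seed=3)
        b = synth_spectrum([(700.0, 10.0, 1.0)], Region.FINGERPRINT,
                           noise_sigma=0.1, seed=3)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValidationError, match="outside grid"):
            synth_spectrum([(2500.0, 10.0, 1.0)], Region.FINGERPRINT)


class TestSynthCohort:
    def test_shapes_and_counts(self):
        cohort, truth = synth_cohort(n_volunteers=2, n_positions=3, seed=4)
        assert len(cohort.volunteers) == 2
        for vol in cohort.volunteers:
            assert len(vol.series) == 3
            for ds in vol.series:
                assert ds.n_depths == 21
                assert ds.depths_um[0] == 0.0 and ds.depths_um[-1] == 40.0
                assert len(ds.spectra_fp) == 21 and len(ds.spectra_hwn) == 21
        # truth profiles: 8 metrics x 2 volunteers x 11 grid points
        assert len(truth.profiles) == 8 * 2 * 11

    def test_same_seed_bit_identical(self):
        c1, t1 = synth_cohort(n_volunteers=1, n_positions=2, seed=9)
        c2, t2 = synth_cohort(n_volunteers=1, n_positions=2, seed=9)
        for ds1, ds2 in zip(c1.volunteers[0].series, c2.volunteers[0].series):
            for a, b in zip(ds1.spectra_fp, ds2.spectra_fp):
                np.testing.assert_array_equal(a.intensities, b.intensities)
        assert t1.band_params.equals(t2.band_params)
        assert t1.profiles.equals(t2.profiles)

    def test_different_seeds_differ(self):
        c1, t1 = synth_cohort(n_volunteers=1, n_positions=1, seed=1)
        c2, t2 = synth_cohort(n_volunteers=1, n_positions=1, seed=2)
        a = c1.volunteers[0].series[0].spectra_fp[5].intensities
        b = c2.volunteers[0].series[0].spectra_fp[5].intensities
        assert not np.array_equal(a, b)
        assert not t1.profiles.value.equals(t2.profiles.value)

    def test_air_region_has_attenuated_keratin_bands(self):
        cohort, truth = synth_cohort(n_volunteers=1, n_positions=1, seed=6,
                                     noise_spec=NoiseSpec.noiseless())
        v = truth.volunteers[0]
        ds = cohort.volunteers[0].series[0]
        # topmost acquisition depth lies well above the surface
        top = ds.spectra_fp[0]
        deep = ds.spectra_fp[-1]
        w = top.wavenumbers
        band = (w >= 1640) & (w <= 1670)
        base = (w >= 1742) & (w <= 1751)
        amp_top = top.intensities[band].max() - top.intensities[base].mean()
        amp_deep = deep.intensities[band].max() - deep.intensities[base].mean()
        assert amp_top < 0.1 * amp_deep

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            synth_cohort(n_volunteers=0, seed=1)


class TestGroundTruthConsistency:
    def test_metrics_recomputed_from_band_params_match_truth_table(self):
        _, truth = synth_cohort(n_volunteers=2, n_positions=1, seed=12)
        bp, md = truth.band_params, truth.metrics_depth
        for vol in truth.volunteers[:1]:
            for depth in (0.0, 10.0, 24.0, 40.0):
                sel = bp[(bp.volunteer == vol.volunteer_id) & (bp.depth_um == depth)]
                fp = [(r.band, r.center, r.fwhm, r.amplitude)
                      for r in sel[sel.region == "fingerprint"].itertuples()]
                hw = [(r.band, r.center, r.fwhm, r.amplitude)
                      for r in sel[sel.region == "hwn"].itertuples()]
                recomputed = _analytic_metrics(fp, hw, truth.calibration)
                for metric, value in recomputed.items():
                    stored = md[(md.volunteer == vol.volunteer_id)
                                & (md.depth_um == depth)
                                & (md.metric == metric)].value.iloc[0]
                    assert value == pytest.approx(stored, rel=1e-12), metric

    def test_depth_metrics_equal_imposed_trajectories(self):
        _, truth = synth_cohort(n_volunteers=1, n_positions=1, seed=8)
        vol = truth.volunteers[0]
        md = truth.metrics_depth
        for depth in (20.0, 30.0):
            pct = 100.0 * (depth - vol.surface_um) / vol.thickness_um
            for metric in METRIC_NAMES:
                if metric == "water_mass_pct":
                    continue
                stored = md[(md.depth_um == depth)
                            & (md.metric == metric)].value.iloc[0]
                assert stored == pytest.approx(
                    float(vol.metric_at(metric, pct)), rel=1e-10), metric

    def test_water_trajectory_has_crowther_signature(self):
        _, truth = synth_cohort(n_volunteers=3, n_positions=1, seed=10)
        for vol in truth.volunteers:
            t = vol.thickness_um
            inside = vol.water_at(t - 0.5) - vol.water_at(t - 1.5)
            beyond = vol.water_at(t + 1.5) - vol.water_at(t + 0.5)
            assert inside == pytest.approx(0.95, rel=1e-9)
            assert beyond == pytest.approx(0.05, rel=1e-9)

    def test_trajectories_within_physical_ranges(self):
        _, truth = synth_cohort(n_volunteers=5, n_positions=1, seed=13)
        for vol in truth.volunteers:
            ss = vol.trajectories["ss_stability"]
            assert np.all((ss >= 0) & (ss <= 1))
            assert np.all(vol.trajectories["cs_ss"] > 0)
            assert 0 < vol.surface_um < 6
            assert 10.0 <= vol.thickness_um <= 25.0
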