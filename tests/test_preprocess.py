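"""Baseline removal and PCA reconstruction behaviour."""

import numpy as np
import pytest

from corneoraman import (Region, Spectrum, ValidationError, auc, hwn_baseline,
                         pca_reconstruct, remove_linear_baseline)
from corneoraman._gaussian import gaussian, gaussian_window_area
from corneoraman.preprocess import AnchorGroup, default_anchor_scheme

from conftest import make_spectrum

GRID = np.arange(400.0, 1800.0, 1.0)
HWN = np.arange(2000.0, 4000.0, 2.0)
GROUP = AnchorGroup(band=(690.0, 712.0), lower=(678.0, 687.0),
                    upper=(716.0, 725.0))


class TestLinearBaseline:
    def test_pure_line_removed_exactly(self):
        s = Spectrum(GRID, 3.0 * GRID + 7.0, Region.FINGERPRINT)
        seg = remove_linear_baseline(s, GROUP)
        assert np.max(np.abs(seg.intensities)) < 1e-9 * np.max(s.intensities)

    def test_line_plus_gaussian_preserves_band_area(self):
        band = (700.0, 8.0, 5.0)
        s = Spectrum(GRID, 0.5 * GRID - 100.0 + gaussian(GRID, *band),
                     Region.FINGERPRINT)
        seg = remove_linear_baseline(s, GROUP)
        got = auc(seg, (690.0, 712.0))
        exact = gaussian_window_area(5.0, 700.0, 8.0, 690.0, 712.0)
        assert got == pytest.approx(exact, rel=5e-3)

    def test_flat_zero_stays_zero(self):
        s = make_spectrum(GRID)
        seg = remove_linear_baseline(s, GROUP)
        assert np.all(seg.intensities == 0.0)

    def test_idempotent(self):
        # the returned segment spans anchor-to-anchor, so the same group can
        # be re-applied and must change nothing
        s = make_spectrum(GRID, [(700.0, 8.0, 5.0)], baseline=3.0)
        once = remove_linear_baseline(s, GROUP)
        twice = remove_linear_baseline(once, GROUP)
        np.testing.assert_allclose(twice.intensities, once.intensities,
                                   atol=1e-10 * np.max(np.abs(s.intensities)))

    def test_commutes_with_positive_scaling(self):
        s = make_spectrum(GRID, [(700.0, 8.0, 5.0)], baseline=2.0)
        seg1 = remove_linear_baseline(s.scaled(7.5), GROUP)
        seg2 = remove_linear_baseline(s, GROUP)
        np.testing.assert_allclose(seg1.intensities, 7.5 * seg2.intensities,
                                   atol=1e-10)

    def test_anchor_outside_span_errors(self):
        s = make_spectrum(np.arange(690.0, 720.0, 1.0))
        with pytest.raises(ValidationError, match="outside"):
            remove_linear_baseline(s, GROUP)

    def test_too_few_anchor_samples_error(self):
        s = make_spectrum(np.arange(400.0, 1800.0, 4.0))  # 2-3 pts per anchor
        with pytest.raises(ValidationError, match="anchor samples"):
            remove_linear_baseline(s, GROUP)

    def test_default_registry_anchors_flank_their_bands(self):
        scheme = default_anchor_scheme()
        for name in ("ss", "cs", "tyr", "cc", "amide1"):
            g = scheme[name]
            assert g.lower[1] <= g.band[0] < g.band[1] <= g.upper[0]
            # >= 5 grid points per anchor at 1 cm-1 sampling
            assert g.lower[1] - g.lower[0] >= 4
            assert g.upper[1] - g.upper[0] >= 4


class TestPcaReconstruct:
    def _group(self, rng, n=10, rank1=False, noise=0.0):
        base = gaussian(GRID, 900.0, 30.0, 1.0) + gaussian(GRID, 1100.0, 50.0, 0.6)
        out = []
        for k in range(n):
            y = base * (1.0 + 0.1 * k) if rank1 else base + 0.05 * np.sin(
                GRID / (50.0 + k))
            y = y + rng.normal(0, noise, GRID.size)
            out.append(Spectrum(GRID, y, Region.FINGERPRINT))
        return out

    def test_full_rank_reconstruction_is_identity(self, rng):
        group = self._group(rng, n=5, noise=0.01)
        recon = pca_reconstruct(group, k=5)
        for a, b in zip(recon, group):
            np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-10)

    def test_identical_spectra_unchanged_any_k(self, rng):
        base = self._group(rng, n=1)[0]
        group = [base] * 6
        for k in (0, 2, 4):
            recon = pca_reconstruct(group, k=k)
            for a in recon:
                np.testing.assert_allclose(a.intensities, base.intensities)

    def test_rank1_signal_denoised_below_sigma(self, rng):
        sigma = 0.05
        clean = self._group(np.random.default_rng(1), n=10, rank1=True)
        noisy = [Spectrum(GRID, c.intensities + rng.normal(0, sigma, GRID.size),
                          Region.FINGERPRINT) for c in clean]
        recon = pca_reconstruct(noisy, k=1)
        rmse = np.sqrt(np.mean([
            (r.intensities - c.intensities) ** 2
            for r, c in zip(recon, clean)]))
        assert rmse < sigma

    def test_group_mean_preserved_exactly(self, rng):
        group = self._group(rng, n=8, noise=0.05)
        recon = pca_reconstruct(group, k=3)
        mean_in = np.mean([s.intensities for s in group], axis=0)
        mean_out = np.mean([s.intensities for s in recon], axis=0)
        np.testing.assert_allclose(mean_out, mean_in, atol=1e-10)

    def test_reconstruction_error_non_increasing_in_k(self, rng):
        group = self._group(rng, n=8, noise=0.05)
        X = np.stack([s.intensities for s in group])
        errs = []
        for k in (1, 2, 4, 6):
            recon = pca_reconstruct(group, k=k)
            R = np.stack([s.intensities for s in recon])
            errs.append(np.sum((X - R) ** 2))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_group_smaller_than_k_errors(self, rng):
        with pytest.raises(ValidationError, match="lower"):
            pca_reconstruct(self._group(rng, n=3), k=4)


class TestHwnBaseline:
    @staticmethod
    def _hinge(x, a, b, c, knot=2810.0):
        return a + b * (x - 3300.0) + c * np.maximum(0.0, x - knot)

    def test_exact_piecewise_line_removed(self):
        y = self._hinge(HWN, 12.0, 0.004, -0.006)
        s = Spectrum(HWN, y, Region.HWN)
        out = hwn_baseline(s)
        assert np.max(np.abs(out.intensities)) < 1e-8

    def test_constant_removed(self):
        s = Spectrum(HWN, np.full(HWN.size, 5.5), Region.HWN)
        out = hwn_baseline(s)
        assert np.max(np.abs(out.intensities)) < 1e-8

    def test_oh_band_areas_preserved_within_one_percent(self):
        bands = [(3277.0, 110.0, 1.0), (3458.0, 100.0, 0.8)]
        y = self._hinge(HWN, 8.0, 0.003, 0.002)
        for c, f, a in bands:
            y = y + gaussian(HWN, c, f, a)
        out = hwn_baseline(Spectrum(HWN, y, Region.HWN))
        got = auc(out, (3150.0, 3600.0))
        exact = sum(gaussian_window_area(a, c, f, 3150.0, 3600.0)
                    for c, f, a in bands)
        assert got == pytest.approx(exact, rel=1e-2)

    def test_missing_anchor_region_errors(self):
        s = make_spectrum(np.arange(2800.0, 3700.0, 2.0), region=Region.HWN)
        with pytest.raises(ValidationError, match="anchor"):
            hwn_baseline(s)
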