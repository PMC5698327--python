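# Methods

`corneoraman` quantifies the depth dependence of keratin secondary and
tertiary structure and of water binding in the human stratum corneum (SC)
from confocal Raman depth series, and ships a synthetic-cohort generator
with exact ground truth so that every stage of the analysis can be validated
without access to in vivo measurements.

## Study design assumed by the pipeline

A cohort consists of volunteers (default 11), each measured at several
lateral skin positions (default 10).  At every position, spectra are
acquired from above the skin surface down to 40 um in 2 um increments, in
two regions: the fingerprint region (400–2000 cm⁻¹, sampled at 1 cm⁻¹ in the
synthetic data) and the high-wavenumber region (HWN, 2000–4000 cm⁻¹, sampled
at 2 cm⁻¹, matching the ~2 cm⁻¹ spectral resolution of confocal Raman
instruments used on skin).

## Pre-processing

**Fingerprint baselines** are local tangent-point lines: for each band
group, 10 samples in each of two flanking anchor windows are pooled and a
straight line is fitted by least squares and subtracted.  Published
protocols select 5–10 tangent points per side manually; for reproducibility
the anchor windows are fixed, documented wavenumber ranges (e.g. 678–687 and
716–725 cm⁻¹ around the 690–712 cm⁻¹ C–S band), chosen ≥ ~4 Gaussian sigmas
away from the neighbouring bands of the SC band inventory.  The returned
segment spans anchor-to-anchor, which makes the operation idempotent.

**PCA denoising** (fingerprint only): all positions of one volunteer at one
nominal depth form a group; each spectrum is replaced by the group mean plus
its projection onto the first k = 4 principal components (mean-centred SVD,
deterministic sign convention).  Groups smaller than k are passed through
unchanged with a log notice.

**HWN baseline**: a continuous two-segment line `a + b·ν + c·(ν − knot)₊`
fitted by weighted least squares with weight 1 inside the anchor regions
2776–2810 and 3800–3900 cm⁻¹ and 0 elsewhere.  The knot sits at 2810 cm⁻¹,
the upper edge of the lower anchor region, so the first segment carries the
lower-region gradient and the second spans the gap to the upper anchors.
This choice is load-bearing: with a mid-spectrum knot (e.g. 3100 cm⁻¹) the
34-cm⁻¹-wide lower anchor must determine a slope that extrapolates ~300 cm⁻¹,
which amplifies anchor noise ×2.5 at the 3277 cm⁻¹ water band (measured:
64-count baseline errors from 26-count channel noise) and biases the
bound-water ratio by several percent even on noise-free spectra.  With the
anchor-edge knot the amplification drops to 0.26×.  The knot remains
configurable.

## Band areas and indicators

Areas under the curve (AUC) use the trapezoid rule on the native grid with
linearly interpolated window endpoints — exact for the piecewise-linear data
model, additive over adjacent windows, and within 0.1% of the closed-form
(erf) Gaussian area for bands resolved by the grid.  Negative post-baseline
areas are integrated as-is (clipping would bias ratios) and logged.

Fixed windows (cm⁻¹): S–S conformers 474–578 with the gauche-gauche-gauche
sub-window 474–508; cysteine C–S 690–712; tyrosine doublet 816–838 (buried)
and 838–874 (exposed); C–C skeletal α-helix 924–946 and β-sheet 952–966;
keratin CH 2910–2965; water OH 3350–3550.

Eight indicators are computed per spectrum:

| indicator | definition | reads out |
|---|---|---|
| `beta_alpha_cc` | AUC(952–966)/AUC(924–946) | β-sheet/α-helix (C–C skeleton) |
| `beta_alpha_amide1` | (AUGC₁₆₇₀+AUGC₁₆₈₅)/AUGC₁₆₅₅ | (β + turns/coils)/α-helix |
| `ss_stability` | AUC(474–508)/AUC(474–578) | gauche-gauche-gauche fraction of S–S |
| `cs_ss` | AUC(690–712)/AUC(474–578) | free cysteine vs disulphide-bonded |
| `tyr_ratio` | AUC(816–838)/AUC(838–874) | buried/exposed tyrosine |
| `ch3_position` | fitted 2930 cm⁻¹ center | keratin folding (lower = more folded) |
| `water_mass_pct` | 100·R/(R+c), R = AUC(3350–3550)/AUC(2910–2965) | water content |
| `bound_water_ratio` | AUGC₃₄₅₈/AUGC₃₂₇₇ | weakly/strongly bound water |

All AUC ratios are invariant under global intensity scaling; `ss_stability`
is confined to [0, 1] on non-negative spectra because its numerator window
is a sub-window of its denominator.  Ratios with non-positive denominators
are flagged undefined (NaN).

**Water calibration.** The mapping from the OH/keratin area ratio R to water
mass % uses the saturating form `water% = 100·R/(R + c)`, the shape forced
by water/(water + protein) mass balance: strictly increasing in R, 0 at
R = 0, asymptotically 100.  The constant c absorbs instrument response and
scattering cross-sections; it is 1.0 by default (instrument-arbitrary units)
and configurable.  Absolute water percentages are therefore
calibration-dependent; depth *profiles* and comparisons are not.

## Constrained Gaussian deconvolution

Overlapping bands are separated by box-constrained nonlinear least squares
(scipy `least_squares`, trf) with an analytic Jacobian.  Center and FWHM of
every component are confined to nominal ± slack boxes; amplitudes are
non-negative.

* **Amide I** (fit range 1580–1720 cm⁻¹): aromatic 1617 ± 7, α-helix
  1655 ± 5, β-sheet 1670 ± 5, turns/random coil 1685 ± 5 cm⁻¹; FWHM boxes
  23 ± 10, 30 ± 6, 15 ± 7, 37 ± 7 cm⁻¹.
* **HWN** (fit range 2800–3700 cm⁻¹): ten bands — the CH stretch family at
  2850, 2880, 2930, 2980, 3063 cm⁻¹ and five OH sub-bands at 3180, 3277
  (strongly bound water, double donor–double acceptor), 3458 (weakly bound,
  single donor–single acceptor), 3550 and 3630 cm⁻¹.  The three sub-band
  centers other than 3277/3458 are not standardised in the literature we
  follow and are configurable (±30 cm⁻¹ boxes); FWHM boxes default to
  nominal ± 15 (CH) and ± 40 cm⁻¹ (OH).

The fit is a deterministic multi-start: start 1 at the nominal values (plus
an optional warm start from the neighbouring depth), further starts jittered
uniformly inside the boxes from a seeded generator, best residual wins
(default 8 starts).  The search stops early once a start's residual reaches
the segment's noise floor — `1.3·n·σ̂²` with σ̂ the second-difference MAD
noise estimate — or falls below 10⁻⁶ of the signal energy; on smooth
synthetic spectra the first start almost always suffices, which keeps the
full-cohort deconvolution (2 × 2310 fits) around 1.5 minutes on one core.
Amplitude standard errors are taken from `σ̂²(JᵀJ)⁻¹` at the solution and
used to flag unreliable derived quantities: the bound-water ratio is
undefined when the 3277 cm⁻¹ amplitude is within 3 standard errors of zero
(otherwise the ratio estimate is unbounded noise, e.g. on near-signal-free
spectra at the skin surface), and the CH₃ position is flagged when its band
amplitude is negligible.

### Identifiability of the Amide I decomposition

The four Amide I components overlap heavily (centers 15–30 cm⁻¹ apart,
FWHM 15–37 cm⁻¹).  Linearised error propagation at the reference
construction (amplitudes 0.2/1.0/0.3/0.25) gives a Cramér–Rao relative
standard deviation of ≈ 16 per unit noise fraction for the
(1670 + 1685)/1655 AUGC ratio: ≈ 16% at SNR 100, ≈ 80% at SNR 20.  This is
a property of the decomposition, not of the optimiser — an independent
implementation (lmfit) converges to the identical global optimum.  The box
constraints truncate the degenerate valley and reduce the observed SNR-20
median ratio error to ≈ 35%, still far above the noiseless case (exact to
10⁻¹²).  Consequently, per-spectrum Amide I ratios should be interpreted
through cohort averages, where the error contracts with the number of
positions and volunteers; single-spectrum values at low SNR are dominated by
decomposition uncertainty.  Band *centers* are better determined (median
error < 0.5 cm⁻¹ at SNR 100, ≈ 1.3 cm⁻¹ at SNR 20).

## Depth landmarks and normalisation

**Surface**: the 1655 cm⁻¹ intensity profile (baseline-corrected) rises from
~0 in air to a plateau inside the skin; the surface is the first upward
crossing of half the profile maximum, refined by linear interpolation.  The
volunteer-level surface is the mean of the per-position estimates.

**SC thickness** follows the water-gradient criterion: moving inward, the
first derivative of the water mass % profile (in %/um) rises through the
steep mid-SC gradient and decays to 0.5 at the SC/SG boundary.  The profile
is smoothed with a 3-point moving average, differentiated with centred
differences, and the *falling* 0.5-crossing after the derivative maximum is
located by linear interpolation.  Taking the falling edge (rather than the
first crossing of any direction) is the physically meaningful reading: the
rising crossing sits mid-SC where the gradient first exceeds the threshold
and marks no boundary.  A normalised convention (threshold on the max-scaled
derivative) is selectable.  Note the 3-point smoothing deepens the crossing
estimate on exponentially decaying (logistic-tail) profiles by
`w·ln(gain)` ≈ 0.8 um for a 2 um tail scale; on profiles that approach the
boundary linearly (as the synthetic cohort does) the estimate is exact up to
noise, because the smoothing/differencing kernel is symmetric about the
slope break.

**Normalisation**: depths are shifted so the surface is 0, scaled by the SC
thickness to % SC depth, and each metric profile is linearly interpolated to
the 0–100% grid in 10% steps.  Grid points outside the measured span are
reported missing (NaN), never extrapolated.  Metric values at depths more
than one increment above the estimated surface are masked before averaging —
they are ratios of noise on signal-free air spectra — while the sample
straddling the surface is kept so that the 0% grid point can be
interpolated.

## Cohort statistics

Per-depth volunteer values are the mean over the volunteer's positions
(robustness to a single outlying position; the order of averaging is not
critical for ratio metrics).  Comparisons between adjacent normalised depths
use the classical two-sided paired Student t-test on per-volunteer values,
traversed from the deepest layers towards the surface (the direction of
corneocyte maturation).  Normality of the paired differences is checked with
the Jarque–Bera statistic `JB = n/6·(S² + K²/4)` against the asymptotic
χ²(2) reference (flagged below n = 30).  p-values are graded ≤ 0.01 highly
significant, ≤ 0.05 significant, ≤ 0.1 trend, otherwise not significant,
with boundary values in the stricter class.  No multiple-testing correction
is applied to the adjacent-depth comparisons; they are reported raw, so
isolated "trend" findings across the 8 × 10 comparison table should be read
accordingly.

## Synthetic cohorts and ground truth

The generator imposes *metric trajectories* — the eight indicators as
piecewise-linear functions of % SC depth — and solves band amplitudes from
them exactly (2 × 2 linear systems in erf window integrals), so the truth
tables and the analysis definitions agree by construction.  Default
trajectory endpoints encode the qualitative depth behaviour reported for
healthy forearm SC: the gauche-gauche-gauche fraction flat near 0.30 in the
deep half and rising to 0.80 at the surface; the C–S/S–S ratio peaking at
0.12 near 70% depth with a 0.08 plateau at 40–10%; the buried/exposed
tyrosine ratio dipping to 0.30 in mid-SC and rebounding to ~0.8 at the
surface; both β/α indicators decreasing from the depth, flat at 40–10% and
ticking up at the surface; the 2930 cm⁻¹ position maximal (most unfolded)
near 70–60% depth; water falling from ~40 mass % at the boundary to ~15 near
the surface; and a U-shaped weakly/strongly-bound water ratio with its
minimum near 30% depth.  Volunteer-level variability multiplies each
trajectory by a draw with 6% CV (additive ±0.3 cm⁻¹ for the CH₃ position),
jitters band centers/widths within the fitting boxes, and draws SC thickness
uniformly from 10–25 um and the surface position from 2.5–5.5 um below the
scan start.

Two constructions are deliberate:

* **Air/skin transition** — all tissue bands are attenuated by a logistic
  of width 1.2 um across the true surface, so the half-maximum surface
  criterion recovers the imposed surface to within the interpolation error.
* **Crowther signature** — the water profile approaches the boundary
  linearly at 0.95 %/um over the final 6 um and continues into the viable
  epidermis at 0.05 %/um.  The midpoint of those slopes equals the 0.5 %/um
  threshold, so the smoothed-derivative crossing sits exactly on the true
  boundary; this is the defining property of the thickness landmark, not a
  tuning choice.

Backgrounds are drawn per spectrum: a linear baseline plus a broad
fluorescence Gaussian (fingerprint), and a two-gradient piecewise-linear
background with its slope change at 3100 cm⁻¹ (HWN).  The HWN background's
kink position deliberately does *not* coincide with the analysis model's
knot, so the correction faces a realistic model/family mismatch; the
residual bound-water error this induces is zero-mean across spectra and
contracts with position averaging.  Additive Gaussian noise defaults to 1%
(fingerprint, ~5 s acquisitions) and 2% (HWN, ~1 s) of the clean maximum
band amplitude.

**Truth tables.** Per acquisition depth the truth record stores the exact
band parameters and the metric values they imply (erf integrals — these
match the imposed trajectories to machine precision).  Truth *profiles* on
the 10% grid are defined as the true per-depth metric values resampled with
the true surface and thickness: the best recovery any analysis of
2-um-sampled data can achieve.  Comparing against the continuous
trajectories instead would charge the pipeline with the irreducible
interpolation error of trajectory bends that fall between samples (up to
~8% at thin SC), which no estimator can remove; the continuous trajectories
remain available for that comparison via `VolunteerTruth.metric_at`.

**What the generator does not emulate** (hence what passing tests do not
show about real skin): confocal signal attenuation and refractive-index
depth distortion; the full band inventory (the 745 ρ(CH₂), 880–890 lipid
and 702 cholesterol bands are omitted because they sit inside default anchor
windows or the C–S window and no computed metric uses them); NMF, urea,
carotenoid and lipid-order bands; fluorescence photobleaching kinetics;
non-Gaussian line shapes; and correlated (shot-noise) noise structure.

## Validation problem sizes

The validation suite runs a full study-design cohort (11 volunteers × 10
positions × 21 depths × 2 regions) at default noise for the geometry and
rank-correlation checks, and a reduced 4-volunteer cohort with the full
10-position averaging at zero noise for the absolute-recovery check
(zero noise needs no volunteer averaging, while the per-spectrum background
draws still average over positions exactly as in the study design).
Statistics calibration uses 200 seeded standard-normal samples of n = 10⁴.

## Known limitations

* Absolute water mass % depends on the configurable calibration constant;
  only profile shapes are calibration-free.
* The Amide I and OH decompositions are near-degenerate; derived ratios at
  low SNR carry large decomposition uncertainty (see above) and should be
  averaged across positions/volunteers.
* The thickness estimator inherits a small deepening bias on profiles whose
  gradient decays exponentially rather than linearly at the boundary.
* The paired-depth statistics are uncorrected for multiplicity by design.
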