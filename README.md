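# corneoraman

Depth-resolved confocal Raman analysis of keratin conformation and water
binding in the human stratum corneum (SC).

Confocal Raman microscopy can profile the outermost skin layer in vivo:
spectra acquired every 2 µm from above the skin surface down to ~40 µm carry
band signatures of keratin's secondary structure (α-helix vs β-sheet),
its tertiary folding state (disulphide conformers, buried/exposed tyrosine,
CH₃ environment), and the amount and hydrogen-bonding state of water.
`corneoraman` implements the full analysis chain for such depth series —
and, because in vivo skin datasets are ethically restricted, a synthetic
cohort generator with exact ground truth that emulates the study design
(11 volunteers × 10 positions × 21 depths × 2 spectral regions), so every
stage is testable end to end.

## What it computes

Per spectrum, eight indicators:

* **β-sheet/α-helix** from the C–C skeletal bands,
  AUC(952–966 cm⁻¹)/AUC(924–946 cm⁻¹), and from a constrained 4-Gaussian
  deconvolution of the Amide I envelope (1580–1720 cm⁻¹; bands at
  1617/1655/1670/1685 cm⁻¹), as (AUGC₁₆₇₀+AUGC₁₆₈₅)/AUGC₁₆₅₅;
* **disulphide stability**: the gauche-gauche-gauche fraction of all S–S
  conformers, AUC(474–508)/AUC(474–578);
* **free cysteine**: C–S/S–S, AUC(690–712)/AUC(474–578);
* **buried/exposed tyrosine**: AUC(816–838)/AUC(838–874);
* **keratin folding**: the fitted center of the 2930 cm⁻¹ CH₃ band from a
  10-band CH/OH deconvolution of 2800–3700 cm⁻¹ (lower = more folded);
* **water mass %** from the calibrated OH/keratin area ratio,
  `100·R/(R+c)` with R = AUC(3350–3550)/AUC(2910–2965);
* **weakly/strongly bound water**: AUGC₃₄₅₈/AUGC₃₂₇₇ from the same
  deconvolution.

Per volunteer, the pipeline locates the skin surface (half-maximum of the
1655 cm⁻¹ keratin profile), estimates SC thickness from the water-gradient
boundary criterion (first derivative of water mass % decaying to 0.5 %/µm),
normalises depth to % SC and interpolates every metric to 10% increments.
Per cohort, it reports mean ± SD profiles and paired t-tests between
adjacent depths (graded ≤0.01 / ≤0.05 / ≤0.1), with Jarque–Bera normality
checks.  Details and design rationale: [`docs/methods.md`](docs/methods.md).

## Worked example

```python
from corneoraman import CohortDepthModel, RunConfig, synth_cohort

cohort, truth = synth_cohort(n_volunteers=3, n_positions=4, seed=42)
results = CohortDepthModel(cohort, RunConfig(seed=42)).fit()
print(results.summary())
```

```
Stratum corneum depth-profile analysis
  volunteers : 3
  thickness  : 22.2 +/- 0.5 um
  metrics    : beta_alpha_cc, beta_alpha_amide1, ss_stability, cs_ss, tyr_ratio, ch3_position, water_mass_pct, bound_water_ratio

  cohort means at the surface (0%), mid-SC (50%) and boundary (100%):
    beta_alpha_cc            0.2328     0.2299     0.2562
    beta_alpha_amide1         0.503     0.4599     0.4885
    ss_stability             0.8165     0.3689     0.2997
    cs_ss                   0.06902    0.09357     0.1157
    tyr_ratio                0.7106     0.2923      0.613
    ch3_position               2928       2930       2930
    water_mass_pct             15.8       28.5      40.47
    bound_water_ratio        0.8817     0.7809       1.16
```

Reading the table: disulphide bonds are mostly in the stable
gauche-gauche-gauche conformation at the surface (0.82) but not at depth
(0.30); water rises from ~16 mass % at the surface to ~40% at the SC/SG
boundary; the 2930 cm⁻¹ CH₃ band sits lower at the surface (more folded
keratin).  The recovered profiles can be compared against
`truth.profiles`, the generator's exact ground truth.

Depth-pair statistics (deepest → surface traversal):

```python
results.adjacent_depth_stats().head(4)
```

```
      metric  depth_a_pct  depth_b_pct         t        p           grade  n
ss_stability        100.0         90.0  1.230424 0.343617 not significant  3
ss_stability         90.0         80.0 -4.659298 0.043107     significant  3
ss_stability         80.0         70.0 -0.663125 0.575455 not significant  3
ss_stability         70.0         60.0 -3.132873 0.088560           trend  3
```

The same pipeline runs from the shell:

```bash
corneoraman simulate --seed 1 --out cohort/
corneoraman analyze --cohort cohort/ --out run/ --seed 1
corneoraman report --run-dir run/
```

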