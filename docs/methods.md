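# Methods

## The measurement model

Magnitude MR images report intensity in uncalibrated grey units (GU), so
all quantitative statements are ratios. The package rests on three
empirical relations established on isolated lungs:

1. **Density–signal.** Lung density ρ = Mass/V (g/mL, from scale mass and
   MRI-segmented volume) is modelled as ρ = a·x + b or ρ = a·x² + b, where
   x is the mean lung signal, optionally divided by the water or muscle
   reference signal from the same scan. The quadratic form is exactly
   a·x² + b with no linear term; the two forms are compared by AICc.
2. **Attenuation–gas fraction.** With the fully deflated scan (0 cmH₂O) as
   reference, MRI_ATT = MRI_CPAP/MRI₀ falls linearly with
   GAS_F = (V_CPAP − V₀)/V_CPAP. Evaluating the fitted line at the
   CT-convention cut-offs 0.1 and 0.5 gives the attenuation thresholds for
   non-aerated and poorly aerated tissue.
3. **Translation to patients.** Collapsed tissue is gasless, so its
   muscle-normalized intensity MRI_ATEL plays the role of the deflated
   reference in vivo: intensity thresholds are
   t = MRI_ATEL × MRI_ATT_threshold. With the canonical MRI_ATEL = 0.92
   and thresholds 0.70 / 0.28 this yields 0.644 / 0.2576, conventionally
   rounded to 0.64 / 0.26.

Classification uses half-open bands: s ≥ t_non is non-aerated,
t_poor ≤ s < t_non poorly aerated, s < t_poor normally or hyper-aerated
(the two are a single merged class — hyperinflated tissue has too little
signal to subdivide reliably). Ties are measure-zero; the convention only
fixes determinism.

## Statistical models

**Mixed models.** Both calibration fits carry a random intercept per lung
(four observations per lung cannot support a random slope) and are
estimated by maximum likelihood, not REML, so AICc is comparable across
fixed-effect structures (statsmodels `MixedLM`). The injury (edema)
covariate enters as a fixed additive intercept shift; its p-value is a
likelihood-ratio test (χ², 1 df) against the fit without the covariate.
AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects plus
variance components. A singular mixed fit — zero between-lung variance, or
zero residual variance as arises with noiseless synthetic data — falls back
to a fixed-effects-only Gaussian ML fit with a logged warning.

**Threshold confidence intervals.** Nonparametric bootstrap over lungs:
resample lungs with replacement, refit the attenuation line, 1000
replicates, seeded. Replicate refits use the fixed-effects (OLS) estimator;
with balanced clusters it is nearly identical to the mixed estimate and
keeps 200-dataset recovery studies tractable. The interval is
t̂ ± t₀.₉₇₅,df·SE_boot with df = n_lungs − 2. We use this t-scaled
construction rather than raw percentile intervals because, with only ~11
clusters, percentile intervals undercover measurably (≈89–90% observed at
nominal 95% in our recovery study) while the t-scaled interval holds the
nominal level. The interval is symmetric about the point estimate and
therefore always contains it.

**Paired tests.** The Wilcoxon signed-rank test uses the normal
approximation without continuity correction, dropping zero differences
(scipy, `method="approx"`, `correction=False`); for six uniformly signed
pairs this gives p = 0.0277, the value clinical tables print as 0.028 (the
exact test would give 0.031). The ROI × time analysis is the classical
univariate two-way repeated-measures ANOVA; for a 2×2 within-subject
design every effect reduces to a paired contrast with F(1, n−1) = t²,
which we compute in closed form (cross-checked against pingouin). When a
contrast has zero variance the test is undefined and p = 1 is returned
with a warning. Pairwise contrasts are Šidák-adjusted, 1 − (1 − p)^m with
m = 2 per family.

**Sample size.** The two-sided Fisher-z formula
n = ⌈((z_{α/2} + z_β)/atanh r)² + 3⌉; |r| = 0.8, α = 0.05, power 0.9
gives n = 12.

## Imaging conventions

* Volumes are axis-aligned grids; voxel-center world coordinate =
  origin + index·spacing. Each axis carries a two-letter anatomical label
  (e.g. "PA" = posterior at index 0). NIfTI input is reoriented to
  closest-canonical; DICOM series are ordered by the projection of the
  image position onto the slice normal (never by instance number), with a
  hard error if inter-slice gaps deviate by more than 1% from the median,
  naming the offending slices.
* Masks inherit geometry from their paired volume; an independent mask
  geometry cannot exist, which makes mismatches loud.
* Analytic ROIs (sphere/cube by volume in cm³, in-slice disc by area in
  cm²) include voxels whose centers fall inside the shape — no
  partial-volume weighting. Derived dimensions: a 2.03 cm³ sphere has
  radius 7.85 mm, the same volume as a cube of side 12.66 mm; a 0.46 cm²
  disc has radius 3.83 mm.
* Magnitude images cannot be negative; negative intensities on load are
  clamped to zero with a logged warning.
* Block merging divides each breath-hold block by its own muscle reference
  *before* concatenation along the inferior–superior axis — the only order
  in which per-block scanner gains cancel. Blocks must be contiguous
  (gap/overlap ≤ half a slice).
* Slightly negative gas fractions (volume measurement noise at low
  pressure) are retained raw for fitting and clamped at −0.05 with a
  warning; classification-time clamping to 0 is a separate concern.

## Synthetic data: what it emulates, and what it does not

**Bench generator** (`ExvivoConfig`): 8 healthy + 3 injured lungs, masses
131.4 ± 34.6 g, deflated specific volume 0.96 mL/g (ρ₀ ≈ 1.04 g/mL),
inflation factors 1 / 3.3 / 2.0 / 1.35 at 0 / 40 / 10 / 2 cmH₂O (gas
fractions ≈ 0 / 0.70 / 0.50 / 0.26, deflation to near total capacity) with
5% lognormal jitter. Signal is painted as the exact inverse of the
analysis-direction quadratic (a = 10⁻⁴ g/mL/GU², b = 0.05 g/mL, ~100 GU
deflated at unit gain), so the density fit is closed-loop recoverable; a
linear mode (s ∝ ρ) provides the analytic attenuation limit
MRI_ATT = 1 − GAS_F (slope −1, intercept 1). Measurement noise: 2% on mean
signal, 1% on segmented volume, 2% per-lung gain spread — chosen once as
realistic bench-measurement error. References: water 300 GU, muscle
200 GU, air floor 1.5 GU; image-space noise is Rician with σ = 1.5 GU,
which reproduces the qualitative SNR ordering (highest deflated,
lowest at 40 cmH₂O).

Note that the two empirical relations are not jointly representable by a
single noiseless forward model: if signal follows the quadratic density
law, the implied attenuation–gas-fraction curve is not the empirical
line with slope −1.05 (the real signal decays faster than proton dilution
alone, plausibly from susceptibility effects at air–tissue interfaces that
the generator does not model). The package therefore also provides a
direct line-sampling generator (`generate_attenuation_records`): per lung,
gas fractions near 0.02 / 0.25 / 0.5 / 0.7 (±0.02) and
att = 0.805 − 1.05·g + b_lung + ε with lung-intercept SD 0.02 and residual
SD 0.03, placing the true thresholds at 0.70 and 0.28. A residual SD of
0.07 instead reproduces a population R² of 0.93 (analytic variance ratio);
that configuration is used for the R²-level check only.

**Thorax phantom** (`InvivoConfig`): 64×64×60 grid at 3×3×5 mm, elliptic
trunk, two lung ellipsoids (TLV ≈ 1.6 L), anterior muscle band painted at
normalized 1.0, linear ventro-dorsal lung gradient 0.08 (ventral) → 0.18
(dorsal), optional dorsal atelectasis blob at 0.92 with a 0.40
poorly-aerated shell, sized by bisection to ≈10% and 16% of TLV. Emitted
as 2–3 contiguous axial blocks with distinct gains (muscle 180 GU) and
Rician noise (default σ = 0.05 in normalized units). Ground-truth
compartments are computed from the painted pre-noise field against the
configured thresholds.

What passing tests on these phantoms shows: the arithmetic, geometry,
model fitting, threshold logic and their statistical calibration are
correct under known truth. What they do not show: robustness to real
anatomy, chest-wall signal attenuation, coil inhomogeneity, motion,
imperfect segmentation, or between-patient muscle variability — phantom
geometry is ellipsoidal by design and segmentation masks are exact.

## Numerical choices and degenerate inputs

* Mixed-model optimization tries BFGS, then Powell, then L-BFGS;
  non-finite coefficients or a singular/degenerate fit trigger the
  fixed-effects fallback.
* Residual variance in ML log-likelihoods is floored at 10⁻³⁰ so that
  noiseless data yield finite (if extreme) AICc values.
* The ventro-dorsal split bisects the anterior–posterior *bounding-box
  extent* of the mask (equal geometric extent, not equal voxel count);
  every lung voxel lands in exactly one half.
* Thresholds are applied at full precision by default; `rounded=True`
  (CLI `--rounded`) applies the two-decimal convenience values for strict
  reproduction of reported numbers.
* Outputs embed package version, seed and a configuration hash; reruns
  with identical inputs are byte-identical.

## Known limitations

* Ex vivo analysis is sample-level (mean signal per lung), not per-voxel
  density mapping. No T1/T2 relaxometry; sequence labels are metadata.
* No automatic segmentation, bias-field correction or pre/post
  registration; pre- and post-operative scans are compared on summary
  statistics only.
* The ex vivo reference-tube ROI placement is configured per scan; reuse
  across pressure levels is a configuration choice.
* Whether the whole-lung normalized mean should average per-block
  normalized voxels (implemented, consistent with per-block muscle
  sampling) or normalize a whole-scan mean by a single muscle value is
  ambiguous in the source protocol; the difference vanishes when block
  gains are equal.
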