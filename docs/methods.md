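# Methods

## The measurement model

A confocal Raman spectrum acquired inside a single organelle is, to good
approximation, a linear superposition of the spectra of the biomolecular
classes present in the probed femtolitre volume, sitting on a slowly varying
autofluorescence background:

    S(ν) = Σᵢ cᵢ Rᵢ(ν − δ) + B(ν) + ε(ν)

where `Rᵢ` are calibrated reference spectra of protein, RNA, DNA and lipid,
`cᵢ ≥ 0` are dimensionless spectral weights, `B` is the fluorescence
baseline, `δ` is a small global wavenumber-registration error between the
measurement and the reference library, and `ε` is channel noise.  Because
each reference is equalized to a *unit weight* — the intensity produced by
100 mg/ml of protein, or 20 mg/ml of RNA, DNA or lipid — the fitted weights
convert directly to absolute concentrations:

    concentrationᵢ [mg/ml] = cᵢ × unit_concentrationᵢ

This is the quantity the downstream statistics operate on.

## Preprocessing

Order is fixed: measured background subtraction (optional) → Savitzky–Golay
smoothing (optional, off by default — the linear fit itself averages channel
noise, and pre-smoothing correlates it) → baseline removal.  Every step is
conservative: the raw trace equals corrected + baseline (+ background)
channel by channel, to 1e-9.

Baseline removal uses asymmetric least squares (ALS): a Whittaker smoother
with second-difference penalty λ and asymmetric weights (p for points above
the baseline, 1−p below), iterated to a stable weight vector (tolerance
1e-6, max 50 iterations; non-convergence raises an error carrying the
iteration count).  Defaults are **λ = 1e8, p = 0.01**.  The stiff penalty is
deliberate: biological Raman bands are dense and Lorentzian-winged, and a
flexible baseline (λ ~ 1e5) climbs into the band wings and biases weights
downward by 10–20% in our recovery studies.  At λ = 1e8 the baseline can
still track a fluorescence hump of a few hundred cm⁻¹ width (off-peak
recovery error ~1% RMS on fixtures with known truth) while leaving band
wings to the fit.  Residual baseline error is absorbed by a low-order
polynomial inside the fit (below).

Replicate handling mirrors the standard acquisition protocol of three
sequential spectra per organelle: replicates are averaged pointwise and the
per-channel sample SD is retained; when ≥3 replicates exist the SDs weight
the fit (w = 1/sd²), otherwise the fit is unweighted.

## The decomposition

At fixed shift δ, the model is linear: a bounded-variable least squares
(BVLS active-set) solve with component columns constrained to cᵢ ≥ 0
(concentrations are physical) and polynomial columns (default cubic,
degree configurable, −1 disables) unconstrained.  δ is the single nonlinear
parameter: it is located by a coarse scan (0.25 cm⁻¹ steps over ±3 cm⁻¹
by default) refined by bounded scalar minimization of the inner optimum
(tolerance 1e-4 cm⁻¹).  On noiseless two-component problems the optimizer
agrees with an exhaustive (c₁, c₂, δ) grid search at (0.001, 0.001,
0.05 cm⁻¹) resolution to within one grid cell; that grid search is kept in
the test suite as an independent oracle.

The in-fit residual polynomial (degree 3 by default) exists to absorb what
baseline correction leaves behind.  The degree was chosen on simulated
recovery studies at SNR 20: a cubic recovers all weights ≥ 0.1 within 5%
relative error in ≥90% of seeded runs through the full ALS-plus-fit chain;
a quadratic leaves a few percent of systematic bias.

Weight uncertainties come from the active-set covariance σ²(XᵀX)⁻¹
restricted to components not pinned at zero (pinned components report SD 0);
σ² is the weighted residual variance, or per-channel replicate SDs when
available.  Components with weight below the detection threshold
(default 0.1 weight units) are *flagged* as undetected, never zeroed or
refit — trace contributions remain visible in the output, marked
unreliable.

Degenerate inputs: an all-zero spectrum yields all-zero weights, residual
zero, and R² reported as 0 (the usual 1 − RSS/TSS is undefined at zero
total variance).  Near-collinear library pairs (cosine ≥ 0.999) are
rejected at library construction.

## Calibration

Pure-compound spectra at known concentrations are projected onto their
common intensity-normalized mean shape; regression of projection amplitude
on concentration, through the origin (zero concentration produces zero
Raman signal), yields intensity per mg/ml.  The returned reference is the
mean shape scaled so that a pure spectrum at the unit concentration fits
weight 1.000 (noiseless case exact to 1e-6).  A single-concentration
calibration is accepted with a warning; a non-positive slope is an error.

## Synthetic data

The generators exist so that every pipeline stage can be tested against
known truth:

- **Component profiles** are sums of Gaussian/Lorentzian/pseudo-Voigt bands
  at canonical positions (phenylalanine 1003, amide I 1660, nucleic-acid
  785/1094/1100/1480/1575, lipid 1063/1301/1440/1745 cm⁻¹ …),
  max-normalized, on a default 600–1800 cm⁻¹ grid at 1 cm⁻¹ spacing.
  Pairwise cosine similarity of the default four-component library stays
  below 0.8.
- **Spectra** follow the forward model exactly: weighted shifted components
  plus a broad Gaussian fluorescence hump plus additive Gaussian channel
  noise (a Poisson mode approximating shot-noise statistics is available).
- **Populations** draw per-cell concentration vectors from a truncated
  multivariate normal (floor 1 mg/ml; lognormal alternative) whose means
  put ±2 SD across the single-cell ranges reported for nucleolus, ER and
  mitochondrion (e.g. nucleolar protein 50–120 mg/ml → μ 85, SD 17.5), and
  whose correlation structure encodes the two phenotype presets: strong
  (~0.8) within-organelle protein–RNA coupling everywhere, strong
  nucleolus–ER coupling in the fibroblast-like preset, near-zero
  cross-organelle coupling in the transformed preset.  The preset pairwise
  targets taken jointly are not a valid correlation matrix; the constructor
  projects to the nearest positive-semidefinite correlation matrix
  (entries move by up to ~0.07) and warns.
- **Time series** are sinusoids c(t) = level + A·sin(2πft + φ) + noise
  sampled at 10-min intervals over 60 min, φ drawn from the seed.  Note a
  sampling subtlety: at 10-min spacing the event estimator (below) detects
  fewer reversals than the 2f extrema/hour of the underlying sinusoid, so
  the demo pipeline uses generator frequencies (2.7 and 1.95 cycles/h)
  calibrated so the *measured* rates sit at the two phenotype levels
  (~4.3 and ~3.0 events/h).

All randomness flows through one seeded `numpy` generator; every generator
returns its truth record, and identical seeds reproduce outputs bit for
bit.

What the generators do *not* emulate: cosmic-ray spikes, detector
etaloning, wavenumber-calibration drift, Mie scattering backgrounds,
organelle-targeting errors, or non-sinusoidal concentration dynamics.
Passing recovery tests therefore demonstrates correctness of the inference
chain under the stated forward model, not robustness to every artifact of
real instruments.

## Statistics

Pearson correlations are computed on concentrations paired strictly by
cell (r is identical on weights, the unit conversion being a positive
scaling), with Fisher-z 95% intervals and the verbal scale |r| < 0.3 weak,
0.3–0.5 moderate, 0.5–0.7 moderate-to-high, > 0.7 strong.  Cross-organelle
correlations use only cells carrying both organelles (pairwise-complete
deletion); when both ends name the same (organelle, analyte) — two
mitochondria of one cell — the first and second records per cell in
acquisition order form the pair.  Zero variance makes r undefined and is
an error, not a NaN.  The full correlation matrix adds Benjamini–Hochberg
FDR flags as supplementary columns, never filters.

Cell-line comparison is classical one-way fixed-effects ANOVA at α = 0.05.
Degenerate cases are defined explicitly: all observations identical → F = 0,
p = 1; zero within-group variance with distinct means → F = ∞, p = 0.  The
two-group case reduces exactly to the squared pooled t statistic, and the
null rejection rate is calibrated (0.05 ± 0.013 over 2000 simulated nulls
in the acceptance suite).

## Dynamics

A time-lapse series is summarized by its exact value range and an
*oscillation rate*: significant reversal events per observed hour
(observed span t_last − t_first, not the nominal session length).  An event
is an interior point where the first differences strictly change sign and
both excursions exceed k·σ (default k = 1), with σ taken from per-point
SDs, a supplied pooled SD, or a robust MAD-of-differences estimate, in that
order of preference.  The counting rule is isolated in one function so that
alternatives (zero crossings of a detrended series, threshold crossings)
can be swapped without touching the rest of the module.  Group comparison
uses a two-sided Mann–Whitney test on per-series rates — at the ~6 series
per group typical of time-lapse sessions, normality is unverifiable.

## Problem sizes and tolerances

Recovery studies run 100 seeded replicates at SNR 20 (strongest clean peak
over noise SD); correlation recovery uses n = 200 cells (Fisher-z 99%
interval checks); ANOVA calibration uses 2000 null replicates; the
event-count oracle sweeps 1000 random series; the demo pipeline uses 8
cells per line and 6 series per analyte and line.  These sizes put Monte
Carlo error comfortably below the tolerances being checked while keeping a
full run in the order of seconds.

## Known limitations

- The nonlinearity in the fit is a single global wavenumber shift; per-band
  shifts or stretches (temperature, calibration nonlinearity) are not
  modelled.
- ALS parameters were chosen on the synthetic forward model; spectra whose
  fluorescence varies on scales comparable to band widths may need a
  smaller λ.
- The oscillation-rate definition is one reasonable operationalization of
  "significant concentration reversals"; rates from other counting rules
  are not directly comparable.
- Absolute concentrations inherit the calibration's assumption that
  reference and in-situ spectra share band shapes; chemical-environment
  shifts inside organelles are not corrected.
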