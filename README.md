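# ramanbca

Quantitative decomposition of single-organelle Raman microspectra into
absolute biomolecular concentrations, with the population and time-lapse
statistics needed to study organelle-to-organelle heterogeneity.

Confocal Raman microspectroscopy can probe a femtolitre volume inside a
living cell — a nucleolus, a patch of endoplasmic reticulum, a single
mitochondrion — without labels or lysis.  The measured spectrum is modelled
as a linear combination of calibrated reference spectra (biomolecular
component analysis, BCA):

    S(ν) = Σᵢ cᵢ Rᵢ(ν − δ) + B(ν) + ε(ν),   cᵢ ≥ 0

with `Rᵢ` the unit-weight reference spectra of protein, RNA, DNA and lipid,
`B` the fluorescence baseline, and `δ` a small wavenumber-registration
shift.  By calibration, spectral weight 1.0 corresponds to 100 mg/ml of
protein and 20 mg/ml of RNA, DNA or lipid, so fitted weights convert
directly to mg/ml.  The package covers the whole chain:

- spectrum and component-library I/O (plain-text formats, JSON manifests)
- preprocessing: background subtraction, Savitzky–Golay smoothing,
  asymmetric-least-squares baseline removal, replicate averaging
- the decomposition engine — non-negative bounded least squares with an
  in-fit residual polynomial and a fitted global shift — exposed as a
  scikit-learn estimator (`BCADecomposer`) and as functions (`fit_lcm`)
- concentration calibration from pure-compound dilution series
- heterogeneity statistics: group summaries, within- and cross-organelle
  Pearson correlations (Fisher-z intervals, BH-FDR flags), one-way ANOVA
  between cell lines
- time-lapse dynamics: concentration ranges and oscillation rates
  (significant reversal events per hour)
- a synthetic-data module generating spectra, populations and time series
  with known ground truth, and a `ramanbca` CLI wiring everything into
  reproducible runs

Intended users: spectroscopists and quantitative cell biologists who want
label-free absolute concentration profiling, and method developers who need
a tested, seedable reference implementation of calibrated spectral
unmixing.

## Worked example

Simulate an organelle spectrum with known composition (protein 0.85,
RNA 0.40, lipid 0.30 in unit weights), a broad fluorescence baseline,
channel noise at SNR 20 and a +1 cm⁻¹ miscalibration — then recover the
composition:

```python
from ramanbca import fit_lcm, preprocess
from ramanbca.synthetic import default_library, simulate_spectrum

lib = default_library()
spectrum, truth = simulate_spectrum(
    lib, {"protein": 0.85, "RNA": 0.40, "lipid": 0.30},
    baseline_amplitude=0.5, noise_sd=0.0425, shift=1.0, seed=11)

pre = preprocess(spectrum)            # ALS baseline removal
result = fit_lcm(pre.processed, lib)  # non-negative LCM fit

for analyte in lib.names:
    print(f"{analyte:8s} weight {result.weights[analyte]:.3f}  "
          f"{result.concentrations[analyte]:6.1f} mg/ml  "
          f"detected={result.detected[analyte]}")
print(f"shift {result.shift:+.2f} cm^-1, R^2 {result.r_squared:.4f}")
```

prints

```
protein  weight 0.858    85.8 mg/ml  detected=True
RNA      weight 0.396     7.9 mg/ml  detected=True
DNA      weight 0.000     0.0 mg/ml  detected=False
lipid    weight 0.315     6.3 mg/ml  detected=True
shift +0.90 cm^-1, R^2 0.9412
```

The weights land within a few percent of the generating truth; DNA, absent
from the mixture, is reported at zero and flagged below the 0.1 detection
threshold; the fitted shift recovers the injected miscalibration.
Multiplying weights by the unit concentrations (100 mg/ml protein,
20 mg/ml RNA/lipid) gives the absolute concentrations shown.

The same flow from the shell, end to end on synthetic data:

```sh
ramanbca pipeline --demo --seed 7 --out demo_run
```

writes a component library, a per-organelle concentration table
(`profiles.csv`), correlation/ANOVA reports under `analysis/`, and
time-lapse oscillation metrics under `dynamics/`, all reproducible
byte-for-byte under the same seed.

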