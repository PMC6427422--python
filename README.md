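# seednir

Viability screening of stored seed lots from FT-NIR absorbance spectra.

Seeds lose viability during long-term storage, and the standard germination
assay takes two weeks and destroys the sample. Near-infrared spectroscopy
offers a non-destructive alternative: chemical changes that accompany seed
aging (protein degradation, changes in bound water) shift the overtone and
combination bands in the 4000–10,000 cm⁻¹ region, so a single-seed absorbance
spectrum carries a viability signature. `seednir` implements the complete
chemometric workflow that turns those spectra into a viable/nonviable
classifier, with a synthetic spectra generator so the whole pipeline can be
exercised, tested and benchmarked without instrument data. It is aimed at
seed-technology and chemometrics practitioners.

## The method

The classifier is **PLS-DA** (partial least squares discriminant analysis):
the 0/1 class code *y* (nonviable = 0, viable = 1) is regressed on the
spectral matrix *X* through latent variables extracted by **NIPALS** with
deflation,

```
X = T Pᵀ + E_X        y = U qᵀ + e_y        ŷ = (x − x̄) b + ȳ ,
b = W (PᵀW)⁻¹ qᵀ
```

where *W* are the X-weights, *P*/*q* the X/y loadings and *T*/*U* the score
matrices. The number of latent variables is selected by stratified k-fold
cross-validation on the calibration set (minimum classification error, ties
to the smaller model). Classification applies a symmetric **±0.5 band**
around each class code: ŷ ≥ 0.5 → viable, ŷ < 0.5 → nonviable; responses
outside [−0.5, 1.5] are assigned to the nearest class and flagged.

Around the core model the package provides:

* **Preprocessing** — max/mean/range normalization, SNV, MSC (reference
  learned from calibration data only), Savitzky–Golay 1st/2nd derivatives,
  and trimming of the information-free region above 9000 cm⁻¹.
* **Diagnostics** — per-sample Hotelling's T² (F-distribution limit) and Q
  residuals (Jackson–Mudholkar limit) at a configurable confidence
  (default 98.9 %); outliers require both statistics beyond their limits.
* **VIP wavelength selection** — variable importance in projection,
  `VIP_j = sqrt( p · Σ_a (w_ja/‖w_a‖)² SSYₐ / Σ_a SSYₐ )`, which satisfies
  Σ VIP² = p, with a threshold scan over 0.8–1.5 scored by cross-validated
  accuracy of the refitted reduced model.
* **Evaluation** — stratified calibration/validation splits, confusion
  matrices with sensitivity, specificity, NER (mean of class sensitivities),
  ER, precision and FPR, and ROC analysis (trapezoid AUC, the
  sensitivity = specificity crossing threshold).
* **Synthetic data** — a generator emulating a three-variety seed lot:
  Gaussian absorption bands near 4536, 4744, 4987, 5174, 5376 and
  6929 cm⁻¹, class-discriminative bands at 4079, 5261 and 7416 cm⁻¹,
  per-seed compositional variability, per-variety baselines, affine scatter,
  smooth baseline wander, heteroscedastic noise, and per-variety germination
  rates (0.87 / 0.89 / 0.84).

## Worked example

```python
import numpy as np
import seednir as sn

# balanced three-variety lot: 124 seeds per variety per class (744 spectra),
# pooled split 260+260 calibration / 112+112 validation, raw vs SG-1st
config = sn.PipelineConfig(n_per_variety_per_class=124,
                           validation_counts=112, max_lv=12,
                           cv_folds=10, seed=1)
result = sn.run_general_model(config)
print(result.comparison[["candidate", "n_lv", "cal_accuracy", "val_accuracy"]])

# screen a 100-seed mixed-variety external lot
lot = sn.simulate_labelled_lot(sn.SimulationConfig(), 40,
                               seed=result.seeds["simulation"] + 1)
keep = np.sort(np.random.default_rng(1).permutation(lot.n_samples)[:100])
report = sn.run_external_test(result, lot.subset(keep))
print(report.cm.layout())
print(f"NER {report.ner:.3f}  sensitivity {report.sensitivity:.3f} "
      f"specificity {report.specificity:.3f}  AUC {report.auc:.3f}")
```

prints

```
candidate  n_lv  cal_accuracy  val_accuracy
      raw    12      0.821154      0.741071
      sg1     7      0.928846      0.866071

                 predicted
               viable  nonviable
true viable        82          6
true nonviable      3          9

NER 0.841  sensitivity 0.932  specificity 0.750  AUC 0.928
```

The Savitzky–Golay 1st-derivative candidate beats the raw spectra on
validation accuracy (0.866 vs 0.741) because the derivative suppresses the
per-sample baseline wander and offset that the affine scatter model injects;
the winning model then screens the unbalanced external lot at a non-error
rate of 0.84 — NER is the mean of the two class-wise recognition rates, so
it is insensitive to the lot's 88:12 class imbalance.

The same workflow is available from the shell:

```
seednir train --out-dir run/            # fit + compare + archive model.json
seednir simulate --lot 40 --seed 5 --out lot.csv
seednir evaluate --model run/model.json --data lot.csv
seednir predict  --model run/model.json --data lot.csv --out pred.csv
```

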