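# Methods

This note records the statistical model, the design of the synthetic data
generator, the numerical choices, and what the test suite does and does not
establish.

## PLS-DA model

The classifier is PLS1 regression of the 0/1 class code on the spectral
matrix, thresholded for classification. Factors are extracted by NIPALS with
deflation; for a univariate response the inner loop converges on the second
iteration, but the general alternating update is kept (tolerance 1e-10 on
the weight vector, at most 500 iterations per component, error on
non-convergence or rank exhaustion). Columns are mean-centered only — no
unit-variance scaling — the standard treatment for absorbance spectra, where
column variance carries band-intensity information that scaling would
destroy. Regression coefficients use the first-*a* prefix identity
`b_a = W_a (P_aᵀ W_a)⁻¹ q_a`, so one fit of the maximum order yields
predictions for every smaller model; cross-validation exploits this.

Latent-variable count: stratified 10-fold cross-validation on the
calibration set, pooled misclassification rate under the ±0.5 rule, minimum
error with ties to the smallest count. Folds are per-class round-robin after
a seeded shuffle; a fold that would lose a class raises an error rather than
silently degrading.

The ±0.5 decision band: ŷ in [0.5, 1.5] → viable, [−0.5, 0.5) → nonviable.
The band rule leaves ŷ outside [−0.5, 1.5] unaddressed; such samples are
assigned to the nearest class code and flagged `outside_baseline`, so
per-class "x of n correct" accounting always totals n. A tie at exactly
ŷ = 0.5 goes to viable (closed lower bound of the viable band).

Diagnostics: Hotelling's T² uses the sample variance (n−1) of the training
scores; its limit is `A(n−1)/(n−A) · F(α; A, n−A)`. Q residuals are squared
distances from the score plane; the limit is the Jackson–Mudholkar
approximation from the eigenvalues of the training residual covariance
(computed via SVD of the deflated matrix, eigenvalues below 1e-12 of the
largest discarded). Confidence defaults to 0.989; it is a plain parameter.
A sample is an outlier only when **both** T² and Q exceed their limits;
single-statistic flags are reported separately for inspection.

## VIP and wavelength selection

`VIP_j = sqrt( p · Σ_a (w_ja/‖w_a‖)² SSY_a / Σ_a SSY_a )` with
`SSY_a = q_a² (t_aᵀ t_a)`. The normalized-weight convention is used because
it is the one under which the identity Σ_j VIP_j² = p holds, and the
identity is asserted on every fitted model. The threshold scan covers
0.8–1.5 in steps of 0.1; each threshold's surviving variables are refitted
(including a fresh LV selection) and scored by cross-validated accuracy;
ties prefer fewer variables, then the smaller threshold. A threshold that
selects nothing is recorded with an undefined accuracy marker rather than
crashing the scan.

## Evaluation conventions

Viable (code 1) is the positive class. NER is the mean of the class-wise
recognition rates, the usual chemometrics definition; on a balanced set it
equals overall accuracy, so both are computed and reported. FPR is
fp/(fp+tn). Metrics with zero denominators are reported as `None`, never
NaN. ROC curves sweep the sorted unique continuous responses with ±infinity
sentinels, classify ŷ ≥ t as viable, and integrate sensitivity over FPR by
trapezoid — which equals the Mann–Whitney pairwise concordance with ties
counted half (asserted against a brute-force oracle). The
sensitivity = specificity crossing threshold is linearly interpolated
between adjacent sweep points.

Splits are per-class seeded permutations supporting either a fraction or
explicit per-class validation counts. Explicit counts are the primary
interface because published protocols typically state counts, and stated
percentages do not always agree with the counts; counts win.

## Synthetic data generator

The generator emulates a naturally aged three-variety triploid watermelon
seed lot measured on a 4000–10,000 cm⁻¹ grid at 4 cm⁻¹ (1501 points;
the point count is an assumption — instruments vary — and is configurable).
Each spectrum is built as:

1. **Shared absorption bands** (Gaussian; centers 4536, 4744, 4987, 5174,
   5376, 6929 cm⁻¹, widths 60–160 cm⁻¹, amplitudes 0.12–0.35 AU) — the C–H
   overtone/combination structure of an oily proteinaceous seed. Gaussians
   rather than Lorentzian/Voigt profiles: NIR condensed-phase bands are
   broad and overlapping, and nothing downstream is sensitive to the line
   shape.
2. **Class-discriminative bands** at 4079, 5261 and 7416 cm⁻¹ whose
   amplitude is higher for nonviable seeds (0.10/0.10/0.08 vs
   0.07/0.07/0.05 AU), plus a global +0.03 AU offset for nonviable spectra,
   so the nonviable class mean sits above the viable mean at every
   wavenumber.
3. **Per-seed compositional variability**: every band amplitude is
   multiplied by a per-seed N(1, 0.2) factor. This is what makes the
   problem realistically hard — the class amplitude differences are of the
   same order as seed-to-seed variation, so class mean spectra nearly
   coincide while single-seed classification stays feasible (~0.85–0.92
   validation accuracy at the default study size).
4. **Variety baselines**: additive offset and gentle slope per variety
   (0 / 0.06 / 0.12 AU), the dominant between-variety difference.
5. **Scatter and drift**: per-sample affine corruption
   x′ = offset + slope·x with offset ~ N(0, 0.05), slope ~ N(1, 0.10) — the
   canonical model MSC/SNV invert — plus a linear-in-wavenumber tilt
   (sd 3·10⁻⁵ AU/cm⁻¹) and **smooth baseline wander**: the first 24 sin/cos
   harmonics over the axis with coefficient sd 0.2/k. The wander matters:
   it is a high-dimensional, low-frequency nuisance (≈48 directions, more
   than any reasonable latent-variable budget), which is precisely the
   regime in which derivative preprocessing is strictly helpful. A purely
   affine scatter model is too easy — a PLS model absorbs any
   low-dimensional linear nuisance in a handful of components and raw
   spectra then classify as well as preprocessed ones, which is not how
   scatter-corrupted NIR behaves in practice.
6. **Noise**: i.i.d. Gaussian, sd 0.004 AU below 9000 cm⁻¹ and 0.04 AU
   above — the tail carries no band information and is trimmed by the
   default pipeline (keep 4000–9000 cm⁻¹; only the upper cut is forced by
   the data, the lower bound stays at the grid start unless configured).

Labels in the balanced generator come by construction; the field-lot
generator draws each seed's viability from its variety's germination rate
(0.87, 0.89, 0.84) to emulate an unbalanced screening lot.

What the generator does **not** model: radiative transfer in the seed coat,
wavelength calibration error, detector nonlinearity, instrument
session-to-session drift between "calibration" and "external" acquisitions,
and any nonlinear class structure. Passing tests therefore demonstrate that
the pipeline implements the intended mathematics and recovers planted
structure under realistic linear corruptions — not that any particular
accuracy would be achieved on real seeds.

## Preprocessing conventions

* A chemometrics "k-point window" for Savitzky–Golay names k points per
  side; the filter window is 2k+1 points (default 9), polynomial order 2
  (the customary choice when unstated), derivative with respect to the grid
  index (per-step), with an option to rescale per cm⁻¹. Edges use
  polynomial extrapolation within the terminal window.
* SNV uses the sample standard deviation (n−1); the choice only rescales
  rows by a constant factor, which the regression absorbs.
* MSC's default reference is the calibration-set column mean, stored with
  the fitted chain and replayed on validation/test data — statistics never
  leak from evaluation data (asserted by a test).
* Candidate chains in the comparison are single-step alternatives
  (raw vs SG-1st by default); arbitrary ordered chains are supported.

## Pipeline and reproducibility

A run pools all varieties, splits once (shared across candidates for a fair
comparison), selects LVs, fits, validates, picks the winner by validation
accuracy (ties → fewer LVs), runs T²/Q diagnostics and optionally the VIP
scan, and serializes a model archive (JSON) containing every array needed
for bit-identical prediction: preprocessing chain with MSC reference and
trim bounds, centering vectors, coefficients, weights/loadings, score
variances, residual eigenvalues, class coding and stage seeds. A single
master seed is split into named per-stage streams (simulation, split, CV)
via `numpy.random.SeedSequence`, so identical config + seed reproduces
archives and reports exactly.

Default problem sizes — 124 seeds per variety per class (744 spectra),
260+260/112+112 pooled split, 10-fold CV up to 12 LVs, a 100-seed external
lot, an 8-point VIP scan — run in a few seconds on one core; they were
chosen to match the emulated study protocol, and the whole suite plus the
acceptance script stays comfortably interactive.

## Known limitations

* Strictly two-class (PLS1); no multi-class or multi-response variant.
* The ±0.5 rule and the ROC threshold analysis both exist, but the deployed
  decision rule is the fixed band, not the ROC-optimal cut.
* The Q-limit approximation assumes approximately Gaussian residuals; with
  very few calibration samples the limit is unstable (as is the T² limit
  for n close to A, which raises an error).
* The generator's corruptions are linear; preprocessing benefits measured
  here are a lower bound on what derivative/scatter correction does for
  genuinely nonlinear instrument effects.
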