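# Methods

This note documents the models, numerical conventions and design choices
behind `torreya_nirs`, and what the synthetic-data experiments do and do not
demonstrate.

## The calibration problem

A diffuse-reflectance NIR spectrum of a kernel sample is an absorbance
vector over 1000–1650 nm (651 points at 1 nm). Protein absorbs near 1200 nm
(C–H stretch) and 1450 nm (N–H stretch), but those bands overlap oil and
water bands, the overall level is dominated by the sample matrix, and the
measurement is distorted by particle-size scatter and baseline drift. The
pipeline therefore (i) preprocesses the spectra, (ii) removes outliers,
(iii) splits samples into calibration and prediction sets, (iv) fits a PLS
regression from spectra to Kjeldahl-reference protein (%), and (v) reports
the standard metric panel.

## Synthetic data generator

The generator produces datasets with the statistical structure the pipeline
assumes, with known ground truth:

    A(λ) = attenuation · ( p · Σ_k amp_k G(λ; c_k, σ_k)
                           + Σ_j conc_j amp_j G(λ; c_j, σ_j) )
    measured = (1 + b) · A + a + drift(λ) + ε

* **Protein bands**: Gaussians at 1200 and 1450 nm, σ = 30 nm, amplitudes
  0.012 and 0.015 AU per % protein. Gaussians are the simplest smooth
  unimodal band shape; only peak positions are physically constrained.
* **Protein distribution**: truncated normal on [6.46, 12.44] % with mean
  9.64 and sd 0.90. The published pool statistics are internally
  inconsistent (pool sd 0.64 vs calibration-set sds 0.88–0.92); the default
  follows the modeling tables, and sd is a parameter.
* **Interferents**: oil C–H at 1210 nm (σ 60, 50 ± 1.5 %), water O–H at
  1440 nm (σ 50, 5 ± 0.5 %), and a very broad matrix band at 1350 nm
  (σ 300, 40 ± 1.5 %) that supplies the ~0.5 AU background level real kernel
  spectra sit on. Concentrations are drawn independently of protein, so no
  single wavelength isolates protein and a multivariate calibration is
  genuinely required (a univariate regression on the 1450 nm channel fails;
  see `test_multivariate_calibration_beats_univariate`).
* **State attenuation**: shell 0.4 < deshelled 0.7 < granules 1.0. The
  shell and pseudotesta mask the kernel signal; attenuation scales the whole
  compositional signal but not the additive distortions, so shelled models
  are systematically weaker, reproducing the qualitative state ordering.
* **Distortions**: multiplicative scatter `(1+b)·A + a` with
  b ~ N(0, 0.20), a ~ N(0, 0.05) — the ±20 % intensity spread typical of
  repacked granular samples (MSC slopes 0.8–1.2); a random per-sample
  quadratic baseline drift with coefficient sd 0.02 AU; i.i.d. Gaussian
  noise with sd 5·10⁻⁴ AU, the scale of a 50-scan-averaged InGaAs
  instrument. The classic affine scatter model is exactly the distortion
  SNV/MSC are constructed to remove, which makes preprocessing efficacy
  testable: the multiplicative interaction b·(protein signal) is irreducible
  for any linear model on raw spectra but vanishes under SNV, so
  scatter-correcting chains consistently beat `Original`.
* **Outlier injection**: spectral outliers get a +1.0 AU Gaussian spike
  (σ = 5 nm, random center). A flat offset is available but is *not* the
  default because SNV and min-max normalization remove flat offsets exactly,
  making them invisible to the PCA-stage screen by construction. Chemical
  outliers get their recorded protein value shifted by ±2.0 % with the
  spectrum untouched, mimicking a reference-method blunder.

**What the generator does not emulate**: Kubelka–Munk/radiative-transfer
nonlinearity, instrument line-shape, temperature/moisture drift of band
positions, wavelength-dependent scatter, or correlation between protein and
other constituents. Passing tests therefore show the pipeline's stages are
correct and well-behaved under the assumed data model, not that any
particular accuracy will be attained on real kernels.

## Preprocessing conventions

* SNV uses the sample (n−1) standard deviation.
* MSC's default reference is the column mean of the set it is fitted on;
  the pipeline fits references on the calibration set and replays them on
  the prediction set, so no prediction-set information leaks into training.
* SG defaults to window 15, polyorder 2 (standard chemometrics choice;
  overridable per step, e.g. `SG(window=21,poly=3)`).
* Derivatives are scaled by the 1 nm step and crop the wavelength axis by
  half a window per side rather than padding, so no extrapolated edge values
  enter the model. Smoothing (deriv 0) keeps the full axis using exact
  polynomial edge fits.
* `Normalize` defaults to per-spectrum min-max; `vector` (unit Euclidean
  norm) is selectable. `Baseline` is a per-spectrum linear detrend.
* Chains apply left to right: `1Der+SNV` differentiates, then standardizes.

## Outlier screen

Stage 1 computes PCA (column-mean-centered SVD, deterministic sign
convention) on state-appropriate preprocessed spectra — Normalize for
shelled, MSC for deshelled, SNV for granules — keeps k = 4 scores (≥ 99 %
of variance on default synthetic data), computes Mahalanobis distances from
the score centroid under the sample score covariance, and flags
MD > median(MD) + 3·MAD(MD) (raw MAD, no consistency scaling; a zero MAD
flags nothing and warns). Stage 2 fits a preliminary PLSR on the survivors
and flags |measured − predicted| > 0.4 % protein, using *out-of-fold*
predictions from 10-fold CV at the one-SE-chosen number of LVs — CV
predictions avoid the self-fitting bias a calibration-fit residual would
have. The 0.4 % gate is interpreted as a strict inequality.

## SPXY split

Joint distance d(i,j) = d_x/max d_x + d_y/max d_y with Euclidean d_x on the
state-default preprocessed spectra and |Δy| on protein. Kennard–Stone
selection: seed with the maximal-d pair, then repeatedly add the sample
whose minimum distance to the selected set is largest; all ties break to
the lowest index, so the split is fully deterministic. Calibration size is
round-half-up of 0.75·n (113 → 85/28). The response extremes are placed in
the calibration set — the joint metric selects them almost always, and when
it does not they are swapped in for the last-selected sample — so the
calibration range always brackets the prediction range. The pipeline splits
once per state (on the same preprocessed spectra used for the PCA screen)
and reuses that split for every chain, keeping the chain grid comparable on
identical sets.

## PLSR and model selection

PLS1 by NIPALS on mean-centered data with deflation; for a univariate
response the inner loop converges in one pass (tolerance 10⁻¹⁰, cap 500
iterations retained for generality). Predictions use the collapsed
coefficient form B = W(PᵀW)⁻¹q, verified in tests against the factor
recursion and, at full rank, against ordinary least squares. A component
with vanishing weight norm stops extraction early with a warning.

Cross-validation uses venetian-blind folds over a seeded shuffle (default
10 folds). RMSECV(A) pools out-of-fold residuals; SE(A) is the sd of
per-fold RMSEs over √folds; the chosen A is the smallest with
RMSECV(A) ≤ min RMSECV + SE(argmin). A fixed-A override
(`n_latent_fixed`) exists for replaying a published LV count.

## Evaluation

R² = 1 − SSres/SStot with the evaluated set's own mean; RMSE divides by n
(not n−1); RPD = sd(prediction-set measured, n−1)/RMSEP;
RER = range(prediction-set measured)/RMSEP; slope from the least-squares
line predicted ~ measured and bias = mean(predicted − measured). Values are
rounded to 2 dp only at serialization. The RER definition follows the
range/RMSEP reading — the only one consistent with the published
shelled/deshelled grids; the published granule-state RPD/RER rows and the
shelled `Original` RER match neither reading and are excluded from the
consistency checks (`torreya_nirs.reference`).

## Problem sizes and determinism

Default experiments use n = 124 samples × 651 wavelengths, the published
pool size. The multi-seed experiments (20 seeds for the pipeline pattern,
100 replicates for outlier recovery, 1000 curves for the one-SE rule, 50
seeds for false-positive rates) complete in seconds to a couple of minutes
on one CPU. Every stochastic step takes an explicit seed and derives all
randomness from `numpy.random.default_rng`; identical config + seed gives
bit-identical datasets, splits and reports.

## Known limitations

* The linear mixing model plus affine scatter makes raw-spectrum PLSR
  stronger than on real data (the distortion is low-rank); the SNV-vs-raw
  margin is correspondingly smaller than a real study would show.
* The residual screen's flag rate scales with the preliminary model's
  error; on noisier configurations the fixed 0.4 % gate can trim a
  noticeable fraction of ordinary samples (it is a parameter).
* Attenuation is the only state effect; real shelled spectra also change
  band shape and scatter statistics.
* MD gating assumes a roughly elliptical score cloud; multimodal score
  distributions would need a different spectral screen.
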