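# Methods

This note documents the models, numerical conventions and design
choices behind `canopylai`, and states precisely what the synthetic
benchmark does and does not demonstrate.

## Problem setting

The target is orchard leaf-area index (LAI, m²/m²) estimated from
multi-date RGB drone orthomosaics. Each sampling point is observed at
L = 3 phenological stages (growth, maturity, fruit-bearing); the
regression label is the final-stage LAI measured on the ground. The
working range is 3.3–5.2 m²/m², i.e. moderate-to-dense canopies where
single greenness indices saturate — the regime the multi-feature,
multi-temporal design is meant to address.

## Radiometric preprocessing

Raw frames carry digital numbers (DN), the sensor's photoelectric
response. A 24-step grayscale panel photographed at flight altitude
anchors a monotone piecewise-linear DN → relative-reflectance curve per
band (exact at the panel knots, clamped to the end reflectances outside
the fitted domain). Piecewise-linear interpolation was chosen over a
parametric (e.g. gamma) fit because it is guaranteed monotone, exact at
the knots, and free of polynomial oscillation. Cross-date illumination
drift — solar angle, atmosphere — is removed by per-band histogram
matching (exact quantile mapping, via scikit-image) against a
designated reference date; the operation is idempotent and removes
exactly the global gain/bias family of distortions the generator
simulates.

Feature tables are min-max normalized with statistics fit on training
rows only. Test values outside the training range map outside [0, 1]
deliberately — clamping would erase out-of-range signal. Constant
features map to 0. Time series missing one stage are filled by linear
interpolation on the stage axis (interior gap: mean of both neighbours;
edge gap: nearest stage); series missing more than one stage are
excluded rather than imputed.

## Features

**Spectral (26).** The three band values plus 23 visible-band indices
computed from the patch's band means ("mean-then-index"; per-pixel
index maps are available behind a flag). Any ratio with a zero
denominator returns 0 and increments a per-feature degeneracy counter,
keeping vectors finite and auditable; the normalized-difference index
carries its own +0.01 guard; the CIVE constant 18.78745 is kept
verbatim; IPCA uses absolute differences.

**Texture (8 × 3 bands).** The gray-level co-occurrence matrix per band:
values quantized to Ng = 32 equal-width levels on the band's observed
range, symmetric co-occurrence counts for the displacement vector
(default (2, 2), a diagonal offset; the 4-direction average is a flag),
normalized to probabilities. Standard Haralick definitions are used for
the eight statistics, with the conventions 0·log 0 = 0 in the entropy
and correlation = 0 when a marginal standard deviation vanishes.
Patch-level values average the statistics over non-overlapping 9×9
windows (a patch smaller than the window contributes one window).
Observed-range quantization makes contrast/dissimilarity/homogeneity
invariant to global additive shifts, which is the desired behaviour
after histogram matching.

The window/displacement sensitivity sweep reports the signed Pearson r
of every texture feature against LAI for each (window, displacement)
setting; settings where the displacement does not fit in the window
admit no co-occurring pair and are reported as NaN rows.

## Screening

Step 1 eliminates a feature only if |r| < 0.10 against LAI in *every*
stage (strict inequality: a feature exactly at the threshold stays).
Step 2 iteratively removes the single feature with the highest variance
inflation factor strictly above 10, recomputing after each removal;
VIF is 1/(1−R²) of the feature regressed with intercept on its
co-features, with an infinity sentinel for perfect collinearity; ties
break to the earliest column for reproducibility. Partial correlations
(least-squares residualization on the retained co-features) verify that
survivors keep an independent association with LAI; residuals whose
variance is numerical dust (≤ 1e-10 of the original scale) are treated
as degenerate and return 0.

## CutMix for regression

A rectangle covering the requested area fraction (default 40%) of the
patch is drawn — aspect ratio uniform in [0.5, 2], position uniform —
and the donor's pixels replace the base's at the same coordinates in
*every* stage patch. The mixed label is y_c = (1−λ)y_a + λy_b with λ
the realized pixel fraction, which is exactly consistent with the
area-proportional definition of LAI. An integer-sided rectangle of the
exact target area does not always exist (e.g. 40% of 32×32 is 410
pixels, which has no factorization with both sides ≤ 32); the
implementation takes the exact-area rectangle whenever one exists and
the nearest achievable area otherwise — the label always uses the exact
realized λ. Augmentation applies to training samples only; synthetic
samples are tagged and carry both parents' point ids so the evaluation
module can verify they never cross the train/test boundary. Features
for augmented samples are recomputed from the mixed pixels, keeping the
area-weighted label physically meaningful.

## The hybrid regressor

Feature mode (default): the CNN branch treats the F × L matrix with
timesteps as channels and convolves along the feature axis (three
blocks, 64/128/256 filters of width 3, ReLU, spatial dropout 0.2, max
pooling /2), flattens, and maps to a 64-unit branch head; the GRU
branch (two layers, 128 and 64 hidden units) consumes the L timesteps
and emits its final hidden state; the meta-learner (dense 128 → 64,
ReLU) fuses the concatenation and a linear unit outputs ŷ. Image mode
swaps the 1-D convolutions for 2-D blocks over the per-stage patch
stack (3L channels; admissible sizes 16–224 px) and feeds the GRU the
per-stage band means and standard deviations. Both modes exist because
the input can legitimately be viewed either as a screened feature
matrix or as resized imagery; each experiment declares its mode.

Training: Adam (lr 0.001, batch 32), MSE loss, early stopping with
patience 20 on a 10% validation split carved from the training data,
at most 500 epochs, best-validation weights restored. Unspecified
details fixed here: ReLU activations, linear output, max-pool 2×2
stride 2, branch heads of one 64-unit layer. A non-finite loss aborts
with diagnostics. The networks are built on an in-package numpy
reverse-mode autodiff engine (float64 throughout, single seeded
generator for initialization, shuffling and dropout), so identical
seeds give bit-identical training histories on the same platform.

Baselines: KNN (k=5, distance-weighted), MLP (128/64, lr 0.01, tol
1e-7), random forest (500 trees) and XGBoost (500 rounds, lr 0.05,
depth 6) wrap scikit-learn/xgboost on flattened inputs; the CNN
baseline is exactly the hybrid's CNN branch plus head; the transformer
baseline (2 encoder layers, 4 heads, width 64, tokens = timesteps in
feature mode or 16×16 patches in image mode) is the smallest credible
encoder for a comparison slot that is named but not specified.

The GRU branch's temporal role is verified by zeroing its output at
prediction time on a signal that only the cross-timestep trajectory
explains: accuracy collapses. The magnitude of such a zero-ablation is
dominated by the off-distribution shift it inflicts on the meta-learner,
so comparative statements between ablation magnitudes across datasets
are not meaningful and are not asserted.

## Evaluation protocol

The 80/20 split is made at the sampling-point level: shuffled whole
points accumulate until the training *sample* count is nearest
round(0.8·N) (ties to the smaller prefix), so no point id appears on
both sides; with 408 points × 4 windows = 1632 samples this yields the
1306/326 partition. The hold-out is fixed once per study; repeated runs
(default 10) vary only initialization and augmentation. 10-fold CV
partitions point ids with fold sizes differing by at most one point.
Metrics: R² = 1 − SS_res/SS_tot, RMSE in LAI units, MAE, MAPE and
rRMSE in percent; mean ± SD over repeats; 95% percentile bootstrap CIs
from 1000 resamples of test positions pooled across repeats; model
pairs compared by a paired bootstrap on squared residuals (1000
resamples, one-sided by declared direction, ties counted conservatively).

## Spatial mapping and metrics

A trained model sweeps the multi-date scene in tiles (stride defaults
to the window; overlaps average; edge tiles read reflection-padded
pixels). Map quality: global Moran's I with row-standardized queen
contiguity (rook available) — +1 smooth, −1 perfectly alternating;
SSIM against a reference map with a 7×7 uniform window and stabilizers
K1=0.01, K2=0.03 on the reference's dynamic range (scikit-image
backend, verified against a direct windowed-formula oracle);
coefficient of variation (population SD / mean); Shannon entropy
(natural log) of the 64-bin equal-width value histogram. Neighbourhood,
window and bin choices are fixed here and exposed in config; published
per-site metric values are data-specific and not reproduced.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not radiative-transfer physics:

- **Orchard scene**: elliptical crowns on a 4.5 m × 1.5 m row grid over
  bare soil; per-point logistic LAI trajectories over the three stages
  with a point-level random intercept, clipped to 3.3–5.2; crown
  reflectance mixes soil and leaf colour by a Beer-Lambert-style
  coverage 1−exp(−0.55·LAI); greenness follows a monotone logistic link
  in LAI; per-date global illumination gain (0.92–1.08) and bias
  (±0.02) — the minimal distortion family histogram matching must
  remove. Defaults mirror the emulated campaign: 96 points, L = 3,
  0.83 cm/px.
- **Texture**: multiplicative Gaussian-blob fields inside each crown.
  Both the amplitude and the granularity are coupled to LAI (the blob
  correlation length shrinks from σ=3 px to σ=0.6 px across the LAI
  range): denser canopies carry finer leaf-scale texture. The
  granularity coupling is what displacement-based GLCM statistics
  detect, because observed-range quantization normalizes a pure
  amplitude coupling away.
- **Sampling-point patches** are rendered crown-centred with the crown
  covering the whole crop, so texture statistics see canopy rather
  than crown/soil edges — matching how field patches are taken at
  crown centres.
- **Panel/camera**: the sensor response is modeled as monotone
  piecewise-linear through the panel's 24 anchor points (anchors on a
  gamma curve, default γ=0.6, scale 255). Because the fitted inverse is
  then the exact inverse of the forward map, the calibration round trip
  is exact to float precision — a deliberate modeling choice that makes
  the calibration contract sharply testable.
- **Continuous-canopy scene**: a closed-canopy variant over a smooth
  latent LAI field (Gaussian-filtered noise rescaled to the LAI range)
  where *every* window is a valid canopy sample. This is the benchmark
  for sliding-window mapping: on the discrete-crown scene, arbitrary
  tiles are soil/crown mixtures far outside the crown-centred training
  distribution, and scoring a model there measures extrapolation
  artifacts rather than mapping skill.

All randomness flows from one seeded generator per call; identical
(config, seed) produce bit-identical rasters and labels.

**What passing tests show — and don't.** The benchmark plants a strong,
low-noise monotone signal; the end-to-end hold-out R² ≈ 0.99 at 300
points demonstrates that the pipeline's plumbing (calibration,
screening, augmentation, training, protocol) recovers a known signal
essentially completely, not that comparable accuracy is attainable on
field data, where leaf angle distributions, shadows, understory
variation and label noise dominate. Conversely, the leakage guards,
oracle equivalences and metric behaviours are exact properties and
transfer as-is.

## Problem sizes and numerical choices

Desk-scale defaults keep the full suite and the acceptance script
within minutes on one CPU: synthetic benchmarks use 40–300 points with
24–32 px patches at a coarsened 4–10 cm/px grid, 150–200 training
epochs, and the reduced-width hybrid in unit tests; the study-scale
constants (96/408 points, 0.83 cm/px, full layer widths, 500 epochs)
remain the package defaults. Tolerances: GLCM and Moran's I match
brute-force oracles exactly / to 1e-12; partial correlation matches the
precision-matrix oracle to 1e-10; metrics match naive loops to 1e-12;
calibration round trips to 1e-6. Tie-breaks: VIF elimination to the
earliest column; point-split prefix ties to the smaller prefix.

## Known limitations

No radiative-transfer realism, shadows, DEM/DSM or photogrammetric
artifacts in the generator; the crown renderer is deliberately minimal.
Image mode at 192–224 px is computationally heavy on the numpy engine —
the input-size study is intended to run at reduced sizes on CPU.
MAPE/rRMSE assume strictly positive labels (guarded anyway). The
transformer baseline is a stand-in architecture, not a tuned
competitor.
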