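# Methods

`nirsolids` implements a complete calibration workflow for predicting the
soluble solids content (SSC, %, °Brix-equivalent) of a liquid food from
portable near-infrared absorbance spectra (900–1800 nm at 1 nm, 901
wavelengths). Because no public reference dataset accompanies this problem,
every quantitative claim in the package is validated on a seeded synthetic
spectrum generator with known ground truth; this note records the models,
the defaults and why, and what the synthetic validation does and does not
demonstrate.

## Synthetic spectrum generator

A spectrum is modelled as a sum of five Gaussian absorption bands on a
scatter baseline:

    x_i(λ) = [ c0 + off_i + slope_i (λ − λ_mid)/1000
               + Σ_b (A_b + k_b · SSC_i) exp(−(λ − μ_b)² / 2σ_b²) ] (1 + g_i)
             + ε_i(λ)

* Band centers μ_b = 980, 1220, 1450, 1530, 1660 nm — water O–H bands at
  980/1450/1530 nm, sugar/organic C–H bands at 1220/1660 nm, where juice
  spectra show their characteristic peaks.
* Band widths σ_b = 30, 28, 26, 24, 22 nm: broad, overlapping, consistent
  with an instrument resolution below 16 nm and liquid-phase band overlap.
  The widths were fixed once so that each configured band produces a
  distinct local maximum of the mean spectrum within 2 nm of its center.
* SSC couplings k_b = −0.004, +0.012, −0.006, +0.003, +0.009 AU/% —
  positive on the sugar C–H bands, negative on the water bands (sugar
  displaces water), giving a ±0.09 AU swing at 1220 nm over the SSC range.
* Noise (defaults chosen once to emulate a portable instrument and held
  fixed): additive white noise 0.005 AU per point, per-sample gain spread
  2%, baseline offset SD 0.02 AU, baseline tilt SD 0.05 AU/1000 nm.
* SSC is drawn from a normal(6.99, 3.79) truncated to [2.20, 16.5] % by
  rejection sampling. Note the asymmetric truncation makes the *realized*
  population mean ≈ 7.69 % and SD ≈ 3.08 %; tests therefore check the
  sample moments against the analytic truncated-normal values, not against
  the parent parameters.
* Abnormal rows ("outliers") are injected at a configurable fraction
  (default benchmark: 4.5% of 180 = 8 rows) as a broad baseline shift plus
  a narrow 8 nm spike, each of magnitude `outlier_magnitude ×
  max(additive_sd, 0.03 AU)`. The absolute floor keeps injected faults
  gross — real abnormal spectra (bubbles, empty cell, stray light) are
  order-0.1 AU events, not multiples of the shot noise.

With all noise terms zero the matrix X is exactly affine in SSC, so a
one-component PLSR must reach machine-precision error — a strong end-to-end
correctness check used throughout the tests.

What passing on this generator does **not** show: robustness to temperature
shifts, nonlinear detector response, wavelength mis-registration, or
chemistry beyond a linear band–SSC coupling. Conclusions about real juice
data require real spectra.

## Preprocessing

* **Savitzky–Golay smoothing** (window 11, polyorder 2 by default): the
  window preserves bands ≥ ~20 nm wide; edge points are fitted on the
  truncated window.
* **Abnormal-sample screen**: PCA scores retaining 95% cumulative variance
  feed an Isolation Forest (100 trees, subsample min(64, n)); the
  ⌈contamination·n⌉ highest anomaly scores (s = 2^(−E[h]/c(ψ))) are
  removed. The variance target default is 0.95, not higher: on
  portable-noise spectra the structured variation (SSC + scatter baselines)
  occupies ~4 components, and pushing cumulative variance to 0.995 admits
  ~100 white-noise components that dilute the forest's splits until real
  outliers are no longer separable. Default contamination 0.045 mirrors an
  8-in-180 abnormal rate typical of handheld acquisition. Recovery of all
  injected outliers is verified at the test seed; a masked borderline case
  can escape at some seeds (observed once in four probed seeds).
* **SPXY partition**: joint distance d = d_X/max d_X + d_y/max d_y,
  initialized at the maximum-distance pair, grown by farthest-point
  (max-min) addition to round(0.7·n) calibration samples; ties break to the
  lowest index so the split is fully deterministic.

## Wavelength selection

* **UVE**: p uniform-noise columns scaled to 1e-10 of the data magnitude
  are appended; leave-one-out PLSR coefficients give a stability
  c_j = mean(b_j)/sd(b_j); real wavelengths are kept where |c_j| exceeds
  the largest noise-column stability. Caveat: at very low component counts
  (≤3) the LOO statistic favors smooth real columns even under a pure-noise
  response; with ≥5 components the null behaves as intended (≤5% retained).
* **VIP**: VIP_j = sqrt(p Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a); threshold
  1 (the mean-square of VIP is identically 1). 
* **CARS**: 100 Monte-Carlo runs; each run fits PLSR on a random 80–90%
  sample subset; the retained-count schedule r_i = a e^(−k i) with r_1 = 1
  and r_N = 2/p; per run, a deterministic coarse cut keeps the top
  2×scheduled wavelengths by |coefficient| and adaptive reweighted sampling
  then draws the scheduled count without replacement with probability
  ∝ |coefficient|; the subset minimizing 5-fold RMSECV wins. A pure
  unique-of-with-replacement resampling step was rejected: with skewed
  coefficient magnitudes it collapses the subset to 2 variables within a
  few runs, detaching the algorithm from its decay schedule. The PLSR
  component count used inside the CV is selected once on the full data and
  held fixed so RMSECV values are comparable across subsets.
* **FS**: identity pass-through (all wavelengths).

## Regressors

* **PLSR** by NIPALS on column-centered (not variance-scaled — absorbance
  units are homogeneous) data; component extraction truncates when the
  residual covariance falls below 1e-12 of its initial norm, which keeps
  exact low-rank problems well-posed. The latent-variable count is chosen
  by 5-fold RMSECV with ties (within 1e-9 relative) resolved to the
  simpler model.
* **GRNN**: Gaussian Nadaraya–Watson; the per-query minimum squared
  distance is subtracted before exponentiation so any spread σ > 0 is
  underflow-safe. σ is grid-searched by the shared 5-fold CV convention
  over multiples (0.05–3) of the data's RMS feature-space scale.
* **LSSVM**: the standard least-squares SVM linear system
  [[0, 1ᵀ],[1, K + I/γ]][b; α] = [0; y] with an RBF kernel
  k(x,z) = exp(−‖x−z‖²/2w²); (γ, w) grid-searched by the same CV.
* **ε-SVR** is provided behind the same fit/predict contract by delegating
  to an established SMO solver.

All regressors are deterministic given inputs and hyperparameters and
invariant to training-row permutation.

## Mixture-of-experts CNN

Backbone: Conv1d(1→2, k5, p2) → BN → ReLU → AvgPool(2) → Conv1d(2→4, k3,
p1) → BN → ReLU → Flatten, giving 4×450 = 1800 features from a 901-point
spectrum. Pooling happens once, after the first convolution, which is the
reading that reproduces all the stated layer shapes (450 after pooling,
1800 flattened). The 1800-vector feeds a gating linear layer (1800 → 2,
softmax) and two expert branches (1800 → 600 linear + ReLU); the fusion is
the convex combination f = Σ_i w_i E_i, and a single linear head maps
600 → 1. Softmax gating is chosen because it makes the fused vector a
convex combination (weights non-negative, summing to 1 — a testable
contract). The ablated CNN control replaces gate/experts/fusion by one
1800 → 600 (+ReLU) path into the same head.

Training: Adam (lr 0.001, β = 0.9/0.999), MSE loss, 500 epochs, batch 32
(full batch below 32), inputs z-scored per wavelength and the target
z-scored with calibration statistics stored in the model; evaluation mode
uses batch-norm running statistics, so predictions are batch-size
independent and deterministic. No early stopping, no auxiliary
gate-balancing loss — MSE through the fusion is the whole objective.

The network is implemented directly in numpy (im2col convolutions,
hand-written backward passes, verified against numerical differentiation
to ~1e-8 relative error). At this size (~2.3 M parameters, ~130 training
rows) CPU training takes a few minutes, and the pure-numpy route keeps the
package dependency-light and bit-reproducible per seed.

## Evaluation

R (Pearson), RMSE, MAE, and RPD = SD/RMSE, with SD the sample standard
deviation (n−1) of the measured values of the evaluated set by default; a
global SD may be supplied instead, since published tables sometimes use
the population SD for every row. RPD ≥ 2.5 is the conventional adequacy
bar for quantitative NIR calibration and is the bar the benchmark is held
to. The paired t-test uses t = d̄/(s_d/√n) with a two-tailed p from
Student's t (n−1 df); p > 0.05 is reported as "no detected systematic
bias". No multiple-testing correction (single comparison).

## Interpretability

* **Loading importance** (PLSR): mean |loading| per wavelength across
  latent variables, normalized to max 1.
* **Shapley attribution** (any regressor): the players are 20 contiguous
  wavelength bins (~45 nm) — band-level attribution is what matters here,
  and small player counts admit an exact enumeration oracle. A coalition's
  value is the model prediction with absent bins imputed from the
  background-mean spectrum (interventional convention), so
  Σ_b φ_b = f(x) − f(x̄_background) exactly. Estimation uses seeded
  permutation sampling (256 permutations per explained sample); each
  permutation's marginal contributions telescope, so the efficiency
  identity holds exactly even for the sampled estimator. Exhaustive
  2^B enumeration is available for B ≤ ~16 and anchors the accuracy tests
  (sampled vs. exact mean deviation < 5% of the largest attribution).

## Benchmark and problem sizes

The reference benchmark (`nirsolids.benchmark.run_moecnn_benchmark`)
generates 180 samples with 8 injected outliers, screens at contamination
0.045 (removes 9), SG-smooths, splits 70/30 by SPXY (120/51), trains the
MoE-CNN for 500 epochs, and evaluates the prediction set. Unit tests
exercise the selectors and kernel models on a 5 nm grid (181 wavelengths,
40–60 samples) and the network on a 10 nm grid (91 points); these sizes
retain the full algorithmic structure while keeping the whole suite within
a few minutes.

## Known limitations

* The generator's linear band–SSC coupling makes the problem close to
  ideal for latent-variable models; nonlinear regressors (GRNN, LSSVM,
  MoE-CNN) are validated for correctness and adequacy here, not for
  superiority over PLSR, which only real data could establish.
* UVE's null behavior at very low component counts (see above).
* The outlier screen ranks by anomaly score and removes a fixed count; it
  does not test whether the removed samples are anomalous in a
  statistically calibrated sense.
* LSSVM and GRNN solve dense n×n systems; they are intended for
  calibration-set sizes in the hundreds, not thousands.
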