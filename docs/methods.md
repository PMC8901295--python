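# Methods

This note documents the models, conventions and design choices behind
`dtfnet`: what is computed, under which assumptions, and why the defaults
are what they are.

## Signal model and conventions

Trials are stacks `(trials × channels × samples)` of epoched EEG in
microvolts with a sampling rate `fs` and ordered 10–20-system channel
labels; class labels are `−1/+1` (left/right imagery). The default epoch
window is the 3–9 s imagery interval of the emulated acquisition protocol
(half-open, sample index `floor(t·fs)`, so 6 s at 500 Hz is exactly 3000
samples). Channel-name matching is case-insensitive with whitespace
stripped, because vendor files vary.

All autoregressive models use the regression sign convention
`x(t) = Σ_k Λ_k x(t−k) + e(t)`. The classical all-pole difference
equation with a leading minus is the same model with negated
coefficients; the sign cancels inside `|H(f)|²`, but one convention rules
the code, and the regression form is what the estimators natively return.
Per-channel means are removed before every fit (AR theory assumes a
zero-mean process). No re-referencing or artifact handling is applied:
channels are used as recorded.

### Estimators

* **Univariate Burg** (via `statsmodels`): minimises summed
  forward+backward prediction-error power through reflection
  coefficients; `noise_var` is the final prediction-error power. Note a
  known property checked by the tests: on a *deterministic* geometric
  decay `x(n) = a·x(n−1)` the order-1 Burg estimate is `2a/(1+a²)`, not
  `a` — Burg is consistent for stationary noise-driven data, which is
  the regime the features operate in.
* **MVAR least squares** (default): one-step-ahead prediction over
  `t = p+1..T`, solved by `lstsq`; innovation covariance from the
  residuals with denominator `T − p`. Chosen as default because the
  multichannel Burg lattice loses precision on long, high-order
  problems.
* **MVAR multichannel Burg** (Vieira–Morf lattice, optional): matrix
  reflection coefficients from Cholesky-normalised forward/backward
  cross-covariances with a Levinson–Whittle update. Agrees with least
  squares to ~1e-3 on well-conditioned simulated data (tested).
* **Order selection**: `AIC(p) = n_eff·ln det Σ_p + 2pN²` with every
  candidate order fitted on the common target window `t ≥ p_max`
  (`n_eff = T − p_max` per trial, pooled across trials), so residual
  determinants are nested and comparable; ties break toward smaller
  `p`. The penalty counts the `pN²` free coefficients. Search ceiling
  defaults to `p_max = 20`; the fallback order when selection is
  disabled is 6 (common practice for sensorimotor EEG).

### DTF

`A(f) = I − Σ_k Λ_k e^{−j2πfkΔt}`, `H(f) = A(f)^{−1}`, and
`γ²_ij(f) = |H_ij|²/Σ_m|H_im|²`. Frequencies are evaluated pointwise at
exact Hz values (the read-out frequencies are discrete components, not
bands); the default read-out grid is 10/15/20/25/30 Hz. A characteristic
matrix with condition number above 1e12 raises an error rather than
returning NaNs: a stable fitted model cannot produce one, so it signals a
broken fit. γ² (not its square root) is the feature value, as that is the
normalised quantity with the row-stochastic interpretation. No surrogate
significance thresholding is applied; raw γ² values feed the classifier.

## Features

* AR features: Burg coefficients `a_1..a_p` per channel, channel-major,
  order fixed at `p = 6` across trials (fixed-length vectors are required
  by the SVM; per-trial order selection would change dimensionality).
* DTF features: one MVAR per trial over all channels, off-diagonal γ²
  entries per read-out frequency (`|freqs|·N·(N−1)` features; diagonal
  self-flow excluded by default, inclusion flag provided). When the order
  policy is "aic", the order is selected once on a calibration subset
  (the first `min(10, n_trials)` trials) and then fixed, keeping the
  feature space identical across trials.
* Fusion: column-wise concatenation over identical trials; the default
  fusion frequency is 30 Hz, the read-out at which DTF features are
  evaluated alongside the AR set.
* Standardisation (zero mean, unit variance per feature) is always fitted
  on training data only and applied to test folds — inside every
  cross-validation fold — so no test statistics leak into training.

## Classification protocol

Linear-kernel SVM (libsvm through scikit-learn), `C = 1.0` by default;
the margin optimiser is deliberately off-the-shelf since the object of
study is the feature construction. Two resampling protocols:
stratified tenfold cross-validation repeated `n_repeats` times with
reshuffled folds (default), and repeated stratified 50/50 train/test
splits. Folds are stratified by class to within one trial, accuracies are
percentages, and the headline number is the arithmetic mean over all
folds and repeats. Fold assignment depends only on the labels and the
scheme seed, so different feature configurations evaluated under the same
scheme see identical partitions and their accuracy differences are
paired. Everything is deterministic given data and seeds.

## Synthetic study conditions

The generator emulates a two-class motor-imagery session: 40 trials per
class, 6 s epochs at 500 Hz, 10–20 labels (2, 10 and 32-channel montages
built in). Each class is a stable MVAR(2) template; trials are
independent realisations with Gaussian innovations (identity covariance
by default), a 500-sample burn-in discarding the zero-initial-condition
transient, and full determinism from a single seed. Because templates are
explicit models, their *analytic* DTF is returned alongside the data as
exact ground truth.

Design choices that matter:

* **Connectivity-only contrast.** The default class difference is a
  directed three-channel ring (C3→C4→Cz→C3, weight 0.4 at lag 1) whose
  orientation flips between classes. Reversing a ring of identically
  coloured nodes leaves every channel's marginal spectrum unchanged, so
  univariate AR features are uninformative *by construction* and any
  discrimination must come from directionality — the cleanest test of
  the DTF pathway. (Verified: AR features sit at chance, median ≈ 50%.)
* **Mild spectral colouring.** All channels share an AR(2) resonance,
  pole radius 0.3 at 12 Hz. The radius is deliberately modest: at 500 Hz
  a sensorimotor rhythm sits at a very low normalised frequency, where a
  near-unit-root resonance has a large low-frequency gain and cannot
  coexist stably with ring couplings of the required ~0.4 weight
  (companion spectral radius ≈ 1.6). Real EEG rhythms are sharper; what
  the tests therefore show is recovery of directed structure in a
  correctly specified MVAR world, not robustness to strong 1/f
  backgrounds, volume conduction or nonstationarity, none of which the
  generator emulates.
* **Fusion condition.** To give AR features a signal too, the fusion
  study condition additionally damps one channel's resonance per class
  (C3 for one class, C4 for the other, radius 0.3 → 0.25) — an ERD-like
  lateralised spectral change. The damping is set so AR features are
  informative (~95–98%) without saturating, keeping the fused-vs-single
  comparison meaningful.
* **Montage sweep condition.** Three direction-flipped rings at graded
  weights: 0.03 touching C3/C4/Cz, 0.10 within the wider motor area
  (F3/FC5/FC6), 0.40 on parieto-occipital channels (P7/P8/Oz) visible
  only to the full 32-channel cap. The weights were chosen so the
  two-channel montage sees only a faint signal while added channels
  carry increasing information, producing the expected non-decreasing
  accuracy across pair2 → motor10 → full32. With fewer samples per trial
  the 32-channel feature space (992 flows from 750-sample fits) is noisy
  enough to *reverse* the last step — estimation noise can outweigh
  added signal — which is why the sweep uses full 3000-sample trials.

## Numerical choices and degenerate inputs

* Band-pass preprocessing is a zero-phase (forward–backward) order-4
  Butterworth and is OFF by default: narrowing the band discards
  autoregressive structure the features rely on and tends to cost
  classification accuracy, so the main pipeline runs unfiltered.
* Constant signals, too-short trials, rank-deficient regressors and
  unstable simulation templates are rejected with named errors rather
  than propagating NaNs; zero-variance features get unit scale and a
  warning.
* Text serialisation uses 17 significant digits (exact for IEEE
  doubles); the `.npz` container round-trips bit-exactly.
* Seeds: trial sets derive entirely from the `SimSpec` seed; evaluation
  folds from the scheme seed plus the repeat index.

## Problem sizes

Unit tests use reduced geometries (12 trials/class, 1.5 s trials); the
acceptance-style checks use the full emulated protocol (40 trials/class,
3000-sample trials) with 20 generator seeds for the accuracy medians,
5000-sample series and 20 seeds for coefficient recovery, and 100 random
stable models for the cofactor-oracle comparison.

## Known limitations

* The generator's world is exactly MVAR: no volume conduction, no 1/f
  background, no ERD/ERS envelope dynamics, no artifacts. Passing tests
  demonstrate correctness of the estimators and the discriminative
  mechanism, not performance on real scalp EEG.
* No partial directed coherence or other Granger-family variants, no
  edge-significance testing, no graph-theoretic summaries, no feature
  selection, no nonlinear kernels, no multiclass support.
* BrainVision/EDF reading delegates to `mne` and is exercised only
  through its epoching logic (the vendor parsers themselves are not
  covered by the test suite, which uses the text and array formats).
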