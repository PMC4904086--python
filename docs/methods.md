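# Methods

This note documents the models, conventions and numerical choices behind
`mibci`, in the spirit of a statistical package's methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and what the generator emulates

The package targets two-class motor-imagery classification, where the
discriminative information is the class-conditional *spatial covariance*
of multichannel EEG (ERD/ERS variance modulation over sensorimotor
cortex). The synthetic generator reproduces exactly this structure and
nothing else: latent sources emit i.i.d. Gaussian samples; class 1 gives
the first `n_discriminative_sources` sources variance `variance_ratio`
(others 1) and class 2 uses the reversed pattern; a fixed random
*orthogonal* mixing (QR of a seeded Gaussian matrix, sign-fixed for
uniqueness) maps sources to channels; isotropic Gaussian sensor noise of
standard deviation `noise_std` is added. Orthogonality makes the
population channel covariances exact —
`Σ_j = A diag(v_j) Aᵀ + noise_std² I` — so whitening, simultaneous
diagonalization and eigenvalue recovery can be checked against closed
forms (e.g. a single 4:1 source in two channels must produce a leading
whitened eigenvalue of 4/5).

Defaults mirror the standard experimental setting the method was designed
for: a two-channel C3/C4-style montage at 100 Hz, 3.5-s epochs
(350 samples), 140 trials per class, one discriminative source with a
moderate 2:1 contrast and noise std 0.5. The generator deliberately omits
band-limited rhythms, 1/f background, artifacts and nonstationarity;
passing tests therefore validate the covariance-driven machinery, not
robustness to real EEG's temporal structure. Real recordings enter
through the fixture reader once epoched externally.

## CSP conventions

* Trial covariance is the raw outer product `E Eᵀ/trace(E Eᵀ)` without
  mean-centering (epoched EEG is approximately zero-mean; the trace
  normalization removes per-trial gain).
* Eigenvalues of the whitened class-1 covariance are sorted descending;
  ties keep stable index order. The projection takes the `m` largest- and
  `m` smallest-eigenvalue eigenvectors; `m_pairs` defaults to 1, the
  maximum possible in the two-channel montage.
* The filter matrix is built from the *second* eigendecomposition
  (`W` rows = selected columns of `U`, transposed, times `P`). A
  formulation that reused the whitening eigenvectors `B` instead would
  skip the simultaneous diagonalization entirely and lose the class
  contrast; the class-specific construction used in RCSP confirms the
  `U`-based reading.
* Filter signs are fixed (first nonzero component positive) so outputs
  are deterministic.
* Log-variance features default to the scale-invariant
  `log(var/Σvar)`; the literal "ratio of logs" normalization that
  sometimes appears in print is available as `variant="as_printed"` but
  is not scale invariant and not recommended.
* Whitening refuses rank-deficient composite covariances (relative
  eigenvalue threshold 1e-10) rather than silently pseudo-inverting.

## RCSP

`Z_j = (1−γ)S_j + (γ/N)tr(S_j)I` with
`S_j = [(1−β)R_j + βR̂_j]/[(1−β)m + β(n−1)m]`, where `R_j` and `R̂_j` are
*sums* of trace-normalized trial covariances over the main subject's `m`
trials and the `(n−1)·m` pooled secondary-subject trials. The shared
denominator is only meaningful as a trial count, which is why every
subject must contribute the same `m` per class; unequal counts are
rejected rather than implicitly reweighted. The `γ` term redistributes
variance onto the diagonal while preserving the trace exactly, so
`γ = 1` leaves a scaled identity and a flat whitened spectrum (no spatial
discrimination), and the spectrum's spread shrinks monotonically in `γ`.
Classification uses both class-specific banks, concatenating their
log-variance features (length `4·m_pairs`); the two filter sets are
constructed independently and no fusion rule is canonical, so plain
concatenation is the minimal choice. With `β = γ = 0` and one subject the
whole construction reduces exactly to CSP (tested to 1e-8).

## SVM

The dual `min ½aᵀQa − eᵀa` (`Q = K ∘ yyᵀ`) under `yᵀa = 0`, `0 ≤ a ≤ C`
is solved by SMO: maximal-violating-pair selection on the incrementally
maintained gradient, analytic two-variable updates, stopping when the
KKT violation gap falls below `tol`. Defaults: `tol = 1e-6` for direct
use, `1e-3` inside the cross-validation loop (speed), `1e-10` when
comparing against the brute-force QP oracle in tests. The kernel is
`exp(−‖x−x′‖²/g²)` — the width enters as `g²`, so external libsvm-style
tools need `gamma = 1/g²`. Bias: mean of `y_i − f₀(x_i)` over free
support vectors, else the midpoint of the interval the bound vectors
admit. Predictions are the sign of the decision value with 0 mapped
to +1. Labels are {1, 2} at the trial level everywhere except inside
this module, which uses {+1, −1} (class 1 ↦ +1).

A note on a tempting invariant: the 0-1 *training error* is not monotone
in `C` (scikit-learn's libsvm reproduces the same non-monotone sequences);
what provably decreases with `C` is the optimal total hinge slack, which
is what the test suite asserts.

## PSO

Global-best topology, constant inertia `w = 0.8`, learning factors
`c1 = 1.5`, `c2 = 1.7`, 50 particles × 100 iterations by default;
`r1, r2` are drawn independently per particle, dimension and iteration.
Velocities are clamped to ±0.2 of the box width per dimension (a standard
default; the clamp bounds are configurable). Positions are clipped to the
box and the offending velocity component zeroed, keeping every candidate
`(C, g)` legal for the SVM. The update without inertia is the special
case `w = 1`. Maximization convention throughout (fitness =
accuracy-like, larger is better); the gbest trace is non-decreasing by
construction and both best and swarm-mean fitness are recorded per
iteration.

## Pipeline

* 60:40 stratified split (per-class proportions to within one trial),
  reproducible from a seed.
* Fitness = stratified k-fold (default 5) cross-validated accuracy, in
  percent, of an SVM at the candidate `(C, g)` on the *training* features.
  Folds are fixed per training run (derived seed), so all particles see
  the same partition and the gbest trace is meaningful.
* The `(C, g)` box spans five decades, so the swarm searches exponents
  (log₁₀ scale) by default; a linear mode exists
  (`log_scale_search=False`) for literal fidelity to a linear reading.
* After the search the SVM is retrained on the full training features at
  the optimum. Filters, hyperparameters and model are all frozen before
  the test set is touched (the evaluation function receives a sealed
  bundle), which the chance-level test verifies end to end.
* Repetition `k` of an experiment derives its seed from the master seed
  via `SeedSequence((seed, k))`; the split uses that seed and the
  swarm/CV use fixed offsets of it. Reports carry per-repetition
  accuracies, the chosen `(C, g)` values, fitness traces and the full
  config echo, with accuracies printed as percent to two decimals.
* Degenerate search boxes (both intervals collapsed to a point) bypass
  the swarm and train directly at that point.

## Problem sizes in tests and the acceptance script

Repeated-ensemble checks (optimizer-vs-grid equivalence, tuning-gain and
chance-level studies) use compact study conditions chosen once: 40-trial-
per-class six-channel datasets with a 1.6:1 contrast and noise std 1.5
(a regime where accuracy sits well below ceiling and the fitness surface
is non-degenerate), 100-sample epochs, swarms of 8–12 particles over
10–20 iterations with 3-fold CV fitness, and 5–20 replicate datasets.
These sizes keep each study to seconds-to-minutes while leaving the
package defaults (50 × 100 swarm, 5-fold CV) untouched. The closed-form
eigenvalue check uses 5000-sample epochs where the sampling error of the
leading eigenvalue is comfortably inside ±0.02.

## Known limitations

* No temporal/spectral preprocessing (band-pass filtering, FBCSP) — the
  package consumes pre-epoched, pre-filtered trials.
* Two classes only; no multi-class CSP or SVM schemes.
* RCSP implements the β/γ covariance-mixing form only (no Tikhonov CSP
  or analytic shrinkage estimators).
* The SMO solver is exact but dense (full kernel matrix); it is meant
  for the small trial counts typical of BCI sessions, not for large-scale
  learning.
* On small noisy training sets, maximizing CV fitness can overfit the CV
  estimate: the swarm's selected `(C, g)` is not guaranteed to beat
  defaults on any single split — only on average across datasets.
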