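# mibci

Two-class motor-imagery EEG classification for brain-computer interfaces:
**Common Spatial Patterns** (and its cross-subject **Regularized CSP**
variant) for feature extraction, an **RBF-kernel support vector machine**
trained by solving its dual problem, and **particle swarm optimization** of
the SVM's penalty and kernel-width parameters. A synthetic trial generator
with analytically known covariance structure makes the whole chain testable
without any EEG recordings.

Intended users: BCI researchers and students who want a small, transparent,
fully tested reference implementation of the classic CSP + PSO-SVM recipe —
every linear-algebra step and solver is visible, deterministic and checked
against independent oracles.

## The method

Imagined movement modulates the variance (band power) of sensorimotor
sources (ERD/ERS), so two imagery classes differ in the *spatial
covariance* of the recorded channels. For trials `E` (channels × samples):

1. **CSP.** Per-trial covariance `R = E Eᵀ / trace(E Eᵀ)`; class means
   `R̄₁, R̄₂`; composite `R_c = R̄₁ + R̄₂ = B λ Bᵀ`; whitening
   `P = λ^(−1/2) Bᵀ`. The whitened class covariances `S_j = P R̄_j Pᵀ`
   share eigenvectors `U` with complementary spectra `λ₁ + λ₂ = I`.
   Filters are rows `uᵀP` for the `m` largest- and `m` smallest-`λ₁`
   eigenvectors; features are `f_j = log(var(Y_j)/Σ_k var(Y_k))` of the
   projected trial `Y = W E`.
2. **RCSP.** Class covariances are regularized before diagonalization:
   `β` mixes in pooled covariances from `n−1` other subjects, `γ` shrinks
   toward a scaled identity (trace-preserving):
   `Z_j = (1−γ)S_j + (γ/N)tr(S_j)I` with
   `S_j = [(1−β)R_j + βR̂_j] / [(1−β)m + β(n−1)m]`.
3. **SVM.** Dual problem
   `min ½ΣΣ a_i a_j y_i y_j K(x_i,x_j) − Σ a_i` subject to `Σ a_i y_i = 0`,
   `0 ≤ a_i ≤ C`, with the Gaussian kernel
   `K(x,x′) = exp(−‖x−x′‖²/g²)` (note: `gamma = 1/g²` in libsvm-style
   parameterizations), solved by SMO with maximal-violating-pair selection.
4. **PSO.** Particles in `(C, g)` space move under inertia `w = 0.8` and
   learning factors `c1 = 1.5`, `c2 = 1.7`
   (`v ← w·v + c1·r1·(pbest−x) + c2·r2·(gbest−x)`), maximizing stratified
   k-fold cross-validated training accuracy; default box
   `C ∈ (0.1, 100)`, `g ∈ (0.01, 1000)`, searched on a log₁₀ scale.
5. **Pipeline.** 60:40 stratified split → fit filters on training trials
   only → swarm-search `(C, g)` → retrain on all training features →
   score held-out trials. Test data never influences filters,
   hyperparameters or model.

## Worked example

`python examples/01_simulate_and_csp.py` — a planted 4:1 variance contrast
behind an orthogonal mixing must yield a leading whitened eigenvalue of
4/(4+1) = 0.8:

```
120 trials, 2 channels, 2000 samples at 100.0 Hz
whitened class-1 eigenvalues: [0.8002 0.2005]
expected from the 4:1 construction: [0.8, 0.2]
```

The eigenvalue 0.8002 says the first spatial filter isolates a direction
carrying ~80% of class 1's share of the combined variance — CSP recovered
the planted source to sampling precision.

`python examples/05_full_pipeline.py` runs the full experiment on noisy
data and prints, e.g.:

```
48 training / 32 test trials
swarm optimum  : C = 32.4254, g = 2.2332
CV fitness     : 83.33% (cross-validated training accuracy)
test accuracy  : 65.62%  (PSO-tuned)
test accuracy  : 65.62%  (default C=1, g=1)
```

Here the swarm's chosen `(C, g)` reaches 83% cross-validated fitness; the
held-out accuracy (65.6%) is lower — an honest measure on 32 noisy test
trials — and matches the default-parameter SVM on this particular split.
Gains from tuning emerge on average over many datasets (see the
acceptance script below).

Other examples: `02_rcsp_shrinkage.py` (γ flattens the CSP spectrum),
`03_svm_dual.py` (XOR via the dual), `04_pso_search.py` (swarm
convergence trace).

## Command line

```sh
mibci simulate --seed 3 --n-trials-per-class 50 --out trials.json
mibci train --data trials.json --out bundle.json
mibci evaluate --bundle bundle.json --data trials.json
mibci experiment --data trials.json --repetitions 10 --out report.json
```

Trials are stored as a plain JSON fixture (manifest + matrices; a
delimited TSV-directory variant exists for interop). Recordings in other
formats (e.g. BCI-competition `.mat` files) should be epoched and
converted to this fixture externally — any tool that can write JSON works;
labels are 1/2, one channels × samples matrix per trial.

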