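"""Full experiment: split, CSP features, PSO-tuned SVM, held-out accuracy.

Generates a moderately noisy two-class set, then compares the swarm-tuned
classifier against an SVM with default parameters (C = 1, g = 1) on the
same 60:40 split.  A small swarm is used so the script runs in seconds;
the package defaults are 50 particles x 100 iterations.
"""

from mibci import (
    PipelineConfig,
    SyntheticConfig,
    evaluate,
    generate_two_class_trials,
    stratified_split,
    train_fixed_svm,
    train_pso_svm,
)

trials = generate_two_class_trials(
    SyntheticConfig(
        n_channels=6,
        n_samples_per_trial=100,
        n_trials_per_class=40,
        variance_ratio=1.6,
        n_discriminative_sources=2,
        mixing_seed=1,
        noise_std=1.5,
    )
)
cfg = PipelineConfig(n_particles=12, max_iterations=20, cv_folds=3, seed=0)
train, test = stratified_split(trials, cfg.train_fraction, seed=cfg.seed)
print(f"{train.n_trials} training / {test.n_trials} test trials")

bundle = train_pso_svm(train, cfg)
print(f"swarm optimum  : C = {bundle.best_C:.4f}, g = {bundle.best_g:.4f}")
print(f"CV fitness     : {bundle.fitness_trace[-1]:.2f}% (cross-validated training accuracy)")
print(f"test accuracy  : {evaluate(bundle, test):.2f}%  (PSO-tuned)")

baseline = train_fixed_svm(train, cfg, C=1.0, g=1.0)
print(f"test accuracy  : {evaluate(baseline, test):.2f}%  (default C=1, g=1)")
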