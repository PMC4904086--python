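"""End-to-end PSO-SVM training on epoched trials.

The procedure, mirroring the standard swarm-tuned SVM recipe for
motor-imagery classification:

1.  Split the trials 60:40 (stratified) into training and test sets.
2.  Fit CSP (or RCSP) spatial filters on the *training* trials only and
    extract log-variance features.
3.  Run PSO over the SVM hyperparameters ``(C, g)`` — penalty
    ``C in (0.1, 100)``, kernel width ``g in (0.01, 1000)`` by default —
    with stratified k-fold cross-validated training accuracy (percent) as
    the fitness each particle maximizes.
4.  Retrain the SVM on the full training feature set at the optimum.
5.  Apply the frozen filters and model to the held-out test trials and
    report accuracy.

Because the (C, g) box spans several decades, the swarm searches the
exponents (log10 scale) by default; positions are decoded back to the
natural scale before every SVM fit, and a linear-scale mode is available.
Test trials are never touched before step 5, so no information leaks into
filters, hyperparameters or model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import csp as _csp
from . import rcsp as _rcsp
from . import svm as _svm
from .csp import FeatureMatrix, SpatialFilterBank
from .errors import ConfigurationError, ValidationError
from .io_epochs import EpochedTrials, select_channels
from .pso import PSOConfig, PSOResult, optimize

_SEED_MOD = 2**31


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the experiment needs; defaults follow the reference setup
    (60:40 split, C in (0.1, 100), g in (0.01, 1000), 50 particles,
    100 iterations, w=0.8, c1=1.5, c2=1.7, 5-fold CV fitness)."""

    feature_method: str = "csp"  # "csp" | "rcsp"
    m_pairs: int = 1
    beta: float = 0.0
    gamma: float = 0.0
    feature_variant: str = "standard"
    channel_subset: tuple | None = None
    train_fraction: float = 0.6
    c_bounds: tuple[float, float] = (0.1, 100.0)
    g_bounds: tuple[float, float] = (0.01, 1000.0)
    n_particles: int = 50
    max_iterations: int = 100
    inertia_w: float = 0.8
    c1: float = 1.5
    c2: float = 1.7
    cv_folds: int = 5
    n_repetitions: int = 1
    seed: int = 0
    log_scale_search: bool = True
    svm_tol: float = 1e-3

    def __post_init__(self):
        if self.feature_method not in ("csp", "rcsp"):
            raise ConfigurationError("feature_method must be 'csp' or 'rcsp'")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        for name, (lo, hi) in (("c_bounds", self.c_bounds), ("g_bounds", self.g_bounds)):
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must be a positive interval")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        for key in ("c_bounds", "g_bounds", "channel_subset"):
            if doc.get(key) is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        for key in ("c_bounds", "g_bounds", "channel_subset"):
            if doc[key] is not None:
                doc[key] = list(doc[key])
        return doc


@dataclass(frozen=True)
class PipelineModel:
    """Frozen prediction bundle: spatial filters + SVM + chosen (C, g)."""

    banks: tuple[SpatialFilterBank, ...]
    model: _svm.SVMModel
    best_C: float
    best_g: float
    fitness_trace: np.ndarray
    mean_fitness_trace: np.ndarray
    config: PipelineConfig

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            "format": "mibci-model-bundle",
            "version": 1,
            "banks": [b.to_dict() for b in self.banks],
            "model": self.model.to_dict(),
            "best_C": self.best_C,
            "best_g": self.best_g,
            "fitness_trace": np.asarray(self.fitness_trace).tolist(),
            "mean_fitness_trace": np.asarray(self.mean_fitness_trace).tolist(),
            "config": self.config.to_dict(),
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            banks=tuple(SpatialFilterBank.from_dict(b) for b in doc["banks"]),
            model=_svm.SVMModel.from_dict(doc["model"]),
            best_C=float(doc["best_C"]),
            best_g=float(doc["best_g"]),
            fitness_trace=np.asarray(doc["fitness_trace"], dtype=float),
            mean_fitness_trace=np.asarray(doc["mean_fitness_trace"], dtype=float),
            config=PipelineConfig(**{
                **doc["config"],
                "c_bounds": tuple(doc["config"]["c_bounds"]),
                "g_bounds": tuple(doc["config"]["g_bounds"]),
                "channel_subset": tuple(doc["config"]["channel_subset"])
                if doc["config"]["channel_subset"] is not None
                else None,
            }),
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Repetition-level results: per-split accuracies and their max/average."""

    accuracies: tuple[float, ...]
    chosen_params: tuple[tuple[float, float], ...]
    fitness_traces: tuple[np.ndarray, ...]
    repetition_seeds: tuple[int, ...]
    config: PipelineConfig

    @property
    def max_accuracy(self) -> float:
        return max(self.accuracies)

    @property
    def average_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "accuracies_pct": list(self.accuracies),
            "max_accuracy_pct": self.max_accuracy,
            "average_accuracy_pct": self.average_accuracy,
            "chosen_params": [{"C": c, "g": g} for c, g in self.chosen_params],
            "fitness_traces": [np.asarray(t).tolist() for t in self.fitness_traces],
            "repetition_seeds": list(self.repetition_seeds),
            "config": self.config.to_dict(),
        }

    def summary(self) -> str:
        lines = [
            f"{'rep':>4} {'accuracy %':>11} {'C':>10} {'g':>12}",
        ]
        for k, (acc, (c, g)) in enumerate(zip(self.accuracies, self.chosen_params)):
            lines.append(f"{k:>4} {acc:11.2f} {c:10.4f} {g:12.4f}")
        lines.append(
            f"max {self.max_accuracy:.2f} %   average {self.average_accuracy:.2f} %"
        )
        return "\n".join(lines)


# -- splitting and fitness ----------------------------------------------


def stratified_split(
    trials: EpochedTrials, train_fraction: float = 0.6, seed: int = 0
) -> tuple[EpochedTrials, EpochedTrials]:
    """Class-stratified train/test split, reproducible from the seed.

    Per-class proportions are preserved to within one trial; every present
    class must land at least one trial on each side.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in trials.classes:
        idx = np.nonzero(trials.labels == label)[0]
        if idx.size < 2:
            raise ValidationError(
                f"class {label} has {idx.size} trial(s); need >= 2 to split"
            )
        k = int(round(train_fraction * idx.size))
        if k == 0 or k == idx.size:
            raise ValidationError(
                f"train_fraction {train_fraction} leaves class {label} empty "
                "on one side of the split"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    return trials.subset(sorted(train_idx)), trials.subset(sorted(test_idx))


def cv_fitness(
    features: FeatureMatrix,
    C: float,
    g: float,
    folds: int = 5,
    seed: int = 0,
    svm_tol: float = 1e-3,
) -> float:
    """Mean stratified k-fold CV accuracy (percent) of an SVM at (C, g).

    This is the fitness PSO maximizes.  Folds depend only on the labels
    and the seed, so every (C, g) candidate sees the same partition.
    """
    x = features.features
    y = _svm.labels_to_pm1(features.labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % _SEED_MOD)
    correct = 0
    for tr, te in skf.split(x, y):
        if len(set(y[tr])) < 2 or len(set(y[te])) < 1:
            raise ValidationError("degenerate CV fold: a class is missing")
        model = _svm.train_svm(
            _svm.TrainingSet(features=x[tr], labels=y[tr]), C, g, tol=svm_tol
        )
        correct += int(np.sum(_svm.predict(model, x[te]) == y[te]))
    return 100.0 * correct / len(y)


# -- feature extraction --------------------------------------------------


def fit_feature_extractor(
    train: EpochedTrials,
    cfg: PipelineConfig,
    secondary: Sequence[EpochedTrials] | None = None,
) -> tuple[SpatialFilterBank, ...]:
    """Fit the spatial filters on training trials only."""
    if cfg.feature_method == "csp":
        cov = _csp.class_mean_covariances(train)
        return (_csp.csp_filters(cov, cfg.m_pairs),)
    z = _rcsp.regularized_covariances(
        train, secondary or [], beta=cfg.beta, gamma=cfg.gamma, m_pairs=cfg.m_pairs
    )
    return _rcsp.rcsp_filters(z, cfg.m_pairs)


def extract_features(
    banks: tuple[SpatialFilterBank, ...],
    trials: EpochedTrials,
    variant: str = "standard",
) -> FeatureMatrix:
    """Log-variance features through one (CSP) or two (RCSP) filter banks."""
    if len(banks) == 1:
        return _csp.features_for_trials(banks[0], trials, variant)
    feats = np.stack(
        [_rcsp.rcsp_features(banks[0], banks[1], t, variant) for t in trials.data]
    )
    return FeatureMatrix(features=feats, labels=trials.labels.copy())


def _maybe_subset(trials: EpochedTrials, cfg: PipelineConfig) -> EpochedTrials:
    if cfg.channel_subset is not None:
        return select_channels(trials, cfg.channel_subset)
    return trials


# -- training ------------------------------------------------------------


def _decode(position: np.ndarray, cfg: PipelineConfig) -> tuple[float, float]:
    if cfg.log_scale_search:
        return float(10.0 ** position[0]), float(10.0 ** position[1])
    return float(position[0]), float(position[1])


def _search_bounds(cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([cfg.c_bounds[0], cfg.g_bounds[0]])
    hi = np.array([cfg.c_bounds[1], cfg.g_bounds[1]])
    if cfg.log_scale_search:
        return np.log10(lo), np.log10(hi)
    return lo, hi


def train_fixed_svm(
    train: EpochedTrials,
    cfg: PipelineConfig,
    C: float,
    g: float,
    secondary: Sequence[EpochedTrials] | None = None,
) -> PipelineModel:
    """Fit filters + SVM at a fixed (C, g), bypassing the swarm.

    The no-search baseline the swarm-tuned classifier is compared against.
    """
    train = _maybe_subset(train, cfg)
    banks = fit_feature_extractor(train, cfg, secondary)
    feats = extract_features(banks, train, cfg.feature_variant)
    model = _svm.train_svm(
        _svm.TrainingSet(
            features=feats.features, labels=_svm.labels_to_pm1(feats.labels)
        ),
        C,
        g,
        tol=cfg.svm_tol,
    )
    return PipelineModel(
        banks=banks,
        model=model,
        best_C=float(C),
        best_g=float(g),
        fitness_trace=np.array([]),
        mean_fitness_trace=np.array([]),
        config=cfg,
    )


def train_pso_svm(
    train: EpochedTrials,
    cfg: PipelineConfig,
    secondary: Sequence[EpochedTrials] | None = None,
) -> PipelineModel:
    """Swarm-search (C, g) by CV fitness on the training set, then retrain.

    Seeds: the swarm uses ``cfg.seed`` and the CV folds ``cfg.seed + 1``
    (mod 2^31), so the whole run is reproducible from one integer.
    """
    train = _maybe_subset(train, cfg)
    banks = fit_feature_extractor(train, cfg, secondary)
    feats = extract_features(banks, train, cfg.feature_variant)
    cv_seed = (cfg.seed + 1) % _SEED_MOD

    collapsed = cfg.c_bounds[0] == cfg.c_bounds[1] and cfg.g_bounds[0] == cfg.g_bounds[1]
    if collapsed:
        best_c, best_g = cfg.c_bounds[0], cfg.g_bounds[0]
        fit = cv_fitness(feats, best_c, best_g, cfg.cv_folds, cv_seed, cfg.svm_tol)
        trace = np.array([fit])
        mean_trace = np.array([fit])
    else:
        lo, hi = _search_bounds(cfg)
        pso_cfg = PSOConfig(
            lower_bounds=lo,
            upper_bounds=hi,
            n_particles=cfg.n_particles,
            max_iterations=cfg.max_iterations,
            inertia_w=cfg.inertia_w,
            c1=cfg.c1,
            c2=cfg.c2,
            seed=cfg.seed % _SEED_MOD,
        )

        def fitness(position: np.ndarray) -> float:
            c, g = _decode(position, cfg)
            return cv_fitness(feats, c, g, cfg.cv_folds, cv_seed, cfg.svm_tol)

        result = optimize(fitness, pso_cfg)
        best_c, best_g = _decode(result.best_position, cfg)
        trace, mean_trace = result.trace, result.mean_trace

    model = _svm.train_svm(
        _svm.TrainingSet(
            features=feats.features, labels=_svm.labels_to_pm1(feats.labels)
        ),
        best_c,
        best_g,
        tol=cfg.svm_tol,
    )
    return PipelineModel(
        banks=banks,
        model=model,
        best_C=best_c,
        best_g=best_g,
        fitness_trace=trace,
        mean_fitness_trace=mean_trace,
        config=cfg,
    )


def evaluate(bundle: PipelineModel, test: EpochedTrials) -> float:
    """Accuracy (percent) of the frozen bundle on held-out trials."""
    if test.n_trials < 1:
        raise ValidationError("test set is empty")
    test = _maybe_subset(test, bundle.config)
    feats = extract_features(bundle.banks, test, bundle.config.feature_variant)
    pred = _svm.labels_from_pm1(_svm.predict(bundle.model, feats.features))
    return 100.0 * float(np.mean(pred == feats.labels))


def repetition_seed(master_seed: int, repetition: int) -> int:
    """Derived seed for repetition k: hash of (master_seed, k), below 2^31."""
    ss = np.random.SeedSequence((int(master_seed), int(repetition)))
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def run_experiment(
    data: EpochedTrials,
    cfg: PipelineConfig,
    secondary: Sequence[EpochedTrials] | None = None,
) -> EvaluationReport:
    """Repeat split -> PSO-SVM training -> evaluation; report max/average.

    Repetition k derives its seed from (cfg.seed, k); the split uses that
    seed and the swarm/CV use offsets of it, so reports are bit-stable
    under the master seed.
    """
    accuracies = []
    params = []
    traces = []
    seeds = []
    for k in range(cfg.n_repetitions):
        rep_seed = repetition_seed(cfg.seed, k)
        seeds.append(rep_seed)
        train, test = stratified_split(data, cfg.train_fraction, seed=rep_seed)
        rep_cfg = dataclasses.replace(cfg, seed=(rep_seed + 1) % _SEED_MOD)
        bundle = train_pso_svm(train, rep_cfg, secondary)
        accuracies.append(evaluate(bundle, test))
        params.append((bundle.best_C, bundle.best_g))
        traces.append(bundle.fitness_trace)
    return EvaluationReport(
        accuracies=tuple(accuracies),
        chosen_params=tuple(params),
        fitness_traces=tuple(traces),
        repetition_seeds=tuple(seeds),
        config=cfg,
    )
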