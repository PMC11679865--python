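"""Per-subject experimental protocol.

For one subject: extract features, shuffle and split the examples 60/20/20
into train/validation/test, let the swarm search the five hyperparameters
with minimum validation cross-entropy as fitness (each particle trains a
fresh model), retrain from scratch with the winning configuration, and
evaluate once on the held-out test set.  Ablation modes reuse the same
protocol with the attention path removed (``no_attention``) or with the
fixed reference configuration and no search (``fixed_params``).

A single master seed drives everything downstream — split permutation,
parameter initialization, dropout streams and swarm draws — so a report is
reproducible bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix

from .errors import AffectLSTMError, DomainError, ShapeError
from .features import FeatureConfig, FeatureSet, build_feature_set, standardize
from .io import EvalReport, SubjectRecording
from .model import FIXED_BASELINE, ModelSpec, build_model
from .pso import PSOConfig, PSOResult, SearchSpace, optimize

MODES = ("proposed", "no_attention", "fixed_params")


@dataclass
class TrainConfig:
    """Gradient-training settings.

    Defaults are the reference protocol: 150 epochs of Adam at learning rate
    1e-4 with categorical cross-entropy on a shuffled 60/20/20 split.
    ``fitness_epochs`` (default = ``epochs``) shortens the training run
    used inside each swarm fitness evaluation.
    """

    epochs: int = 150
    learning_rate: float = 1e-4
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    fitness_epochs: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise DomainError("epochs must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DomainError(f"fractions must sum to 1, got {self.fractions}")
        if self.fitness_epochs is None:
            self.fitness_epochs = self.epochs


@dataclass
class ExperimentConfig:
    """Everything a subject run needs besides the recording and the seed."""

    train: TrainConfig = field(default_factory=TrainConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    space: SearchSpace = field(default_factory=SearchSpace.default)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    fixed: dict = field(default_factory=lambda: dict(FIXED_BASELINE))
    group_split: bool = False  # per-trial grouped split (leakage-averse)
    dtype: type = np.float32


def desk_profile() -> ExperimentConfig:
    """Desk-scale settings for synthetic experiments on one CPU.

    Small search space (units <= 32), 5 particles x 3 iterations,
    10-epoch fitness trainings and a 30-epoch final training at learning
    rate 3e-3 — the same protocol at a size where a full subject run takes
    seconds to minutes rather than days.
    """
    return ExperimentConfig(
        train=TrainConfig(epochs=30, learning_rate=3e-3, fitness_epochs=10),
        pso=PSOConfig(particles=5, iterations=3),
        space=SearchSpace.desk(),
        fixed={"units1": 16, "units2": 12, "dense_units": 8,
               "dropout_rate": 0.2, "batch_size": 32},
    )


def split_data(
    fs: FeatureSet | int,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    *,
    group_by_trial: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded shuffled partition of example indices into train/val/test.

    Train and validation sizes are floors of their fractions; the remainder
    is the test set, so the three sets are disjoint and exhaustive.  The
    default shuffles individual segments, mirroring the reference protocol.
    ``group_by_trial`` instead keeps all segments of a trial in one
    partition (a leakage-averse alternative: segments of a trial share the
    subtracted baseline, so a per-segment split lets trial identity leak
    into the test set).
    """
    n = fs if isinstance(fs, int) else fs.features.shape[0]
    if n < 1:
        raise DomainError("cannot split an empty feature set")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DomainError(f"fractions must sum to 1, got {fractions}")
    if group_by_trial:
        if isinstance(fs, int):
            raise DomainError("group_by_trial needs a FeatureSet with provenance")
        trials = fs.provenance[:, 0]
        order = np.random.default_rng(seed).permutation(np.unique(trials))
        n_train = int(math.floor(fractions[0] * len(order)))
        n_val = int(math.floor(fractions[1] * len(order)))
        parts = (order[:n_train], order[n_train:n_train + n_val],
                 order[n_train + n_val:])
        train, val, test = (np.nonzero(np.isin(trials, p))[0] for p in parts)
    else:
        perm = np.random.default_rng(seed).permutation(n)
        n_train = int(math.floor(fractions[0] * n))
        n_val = int(math.floor(fractions[1] * n))
        train = perm[:n_train]
        val = perm[n_train:n_train + n_val]
        test = perm[n_train + n_val:]
    if not isinstance(fs, int):
        present = set(fs.class_ids[train].tolist())
        if present != set(range(fs.n_classes)):
            warnings.warn(
                f"training split is missing class(es) "
                f"{sorted(set(range(fs.n_classes)) - present)}", stacklevel=2)
    return train, val, test


def train_model(
    spec: ModelSpec,
    batch_size: int,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    *,
    epochs: int | None = None,
    seed: int = 0,
    dtype=np.float32,
):
    """Train a model and return ``(model, history, best_val_loss)``.

    ``history`` holds per-epoch mean training loss and validation
    cross-entropy.  The parameters of the best-validation epoch are
    restored into the returned model; with ``epochs=0`` the untrained
    model is scored on the validation set only (loss ~ ln K for balanced
    classes under a near-uniform head).
    """
    from .nn import Adam, cross_entropy

    n_epochs = cfg.epochs if epochs is None else epochs
    model = build_model(spec, seed=seed, dtype=dtype)
    history = {"train_loss": [], "val_loss": []}
    val_loss = cross_entropy(model.predict_proba(X_val), y_val)
    best_val, best_state = val_loss, model.get_state()
    if n_epochs == 0:
        return model, history, float(val_loss)
    adam = Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([seed, 0x5F]).generate_state(1))
    n = len(y_train)
    batch_size = max(1, min(int(batch_size), n))
    for epoch in range(1, n_epochs + 1):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss = model.loss_and_grads(X_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise AffectLSTMError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(seed={seed}, spec={spec})")
            adam.step()
            losses.append(loss)
        val_loss = cross_entropy(model.predict_proba(X_val), y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val, best_state = val_loss, model.get_state()
    model.set_state(best_state)
    return model, history, float(best_val)


def _spec_from_params(params: dict, fs: FeatureSet,
                      attention: bool) -> tuple[ModelSpec, int]:
    spec = ModelSpec(
        units1=int(params["units1"]),
        units2=int(params["units2"]),
        dense_units=int(params["dense_units"]),
        dropout_rate=float(params["dropout_rate"]),
        num_classes=fs.n_classes,
        timesteps=fs.features.shape[1],
        channels=fs.features.shape[2],
        attention=attention,
    )
    return spec, int(params["batch_size"])


def pso_fitness(
    fs: FeatureSet,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: ExperimentConfig,
    *,
    attention: bool = True,
    seed: int = 0,
):
    """Build the swarm's fitness: decoded hyperparameters -> best validation
    cross-entropy after a ``fitness_epochs`` training on the fixed split.

    The closure touches only the train and validation partitions; the index
    sets it is allowed to read are exposed as ``fitness.indices_used`` so
    callers can assert the test set never leaks into the search.  Failures
    to build or train surface as +inf with the reason recorded on
    ``fitness.failures``.
    """
    train_idx, val_idx, _ = split
    X = fs.features
    y = fs.class_ids
    X_train, y_train = X[train_idx], y[train_idx]
    X_val, y_val = X[val_idx], y[val_idx]
    failures: list[tuple[dict, str]] = []

    def fitness(decoded: dict) -> float:
        try:
            spec, batch = _spec_from_params(decoded, fs, attention)
            _, _, best_val = train_model(
                spec, batch, X_train, y_train, X_val, y_val, cfg.train,
                epochs=cfg.train.fitness_epochs, seed=seed, dtype=cfg.dtype)
            return best_val
        except AffectLSTMError as exc:
            failures.append((decoded, str(exc)))
            return math.inf

    fitness.indices_used = np.sort(np.concatenate([train_idx, val_idx]))
    fitness.failures = failures
    return fitness


def run_subject(
    rec: SubjectRecording,
    mode: str = "proposed",
    cfg: ExperimentConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Run the full protocol for one subject and return its report.

    ``proposed``: swarm search then final training with the winning
    hyperparameters; ``no_attention``: identical but the model drops the
    attention/context path; ``fixed_params``: no search, the fixed
    reference configuration.
    """
    if mode not in MODES:
        raise DomainError(f"mode must be one of {MODES}, got {mode!r}")
    cfg = cfg or ExperimentConfig()
    child = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    split_seed, fit_seed, final_seed, pso_seed = (int(v) for v in child)

    fs = build_feature_set(rec, cfg.features)
    split = split_data(fs, cfg.train.fractions, seed=split_seed,
                       group_by_trial=cfg.group_split)
    train_idx, val_idx, test_idx = split
    X, y = fs.features, fs.class_ids
    if not fs.standardized:
        # leakage-safe mode: statistics from the training partition only
        X, stats = standardize(X, scope_indices=train_idx)
        fs = replace(fs, features=X, stats=stats, standardized=True)
        X = fs.features

    attention = mode != "no_attention"
    loss_trace: list[tuple[int, float]] = []
    n_evaluations = 0
    if mode == "fixed_params":
        best_params = dict(cfg.fixed)
    else:
        fitness = pso_fitness(fs, split, cfg, attention=attention,
                              seed=fit_seed)
        assert np.intersect1d(fitness.indices_used, test_idx).size == 0
        result: PSOResult = optimize(
            fitness, cfg.space, replace(cfg.pso, seed=pso_seed))
        best_params = result.best_params
        loss_trace = result.trace
        n_evaluations = len(result.log)

    spec, batch = _spec_from_params(best_params, fs, attention)
    model, history, _ = train_model(
        spec, batch, X[train_idx], y[train_idx], X[val_idx], y[val_idx],
        cfg.train, seed=final_seed, dtype=cfg.dtype)
    y_pred = model.predict(X[test_idx])
    confusion = confusion_matrix(y[test_idx], y_pred,
                                 labels=np.arange(fs.n_classes))
    accuracy = float(np.trace(confusion) / confusion.sum())
    return EvalReport(
        subject_id=rec.subject_id,
        accuracy=accuracy,
        confusion=confusion,
        best_hyperparams=best_params,
        loss_trace=loss_trace,
        seed=seed,
        mode=mode,
        n_evaluations=n_evaluations,
    )


@dataclass
class ExperimentResult:
    """Across-subject aggregate: accuracy statistics and the element-wise
    summed confusion matrix."""

    reports: list[EvalReport]
    mean: float
    std: float
    max: float
    min: float
    confusion: np.ndarray

    def summary(self) -> dict:
        return {
            "subjects": len(self.reports),
            "mean": self.mean,
            "std": self.std,
            "max": self.max,
            "min": self.min,
            "confusion": self.confusion.tolist(),
        }


def aggregate(reports: list[EvalReport]) -> ExperimentResult:
    """Mean/std/max/min accuracy across subjects plus the summed confusion."""
    if not reports:
        raise DomainError("aggregate needs at least one report")
    shapes = {r.confusion.shape for r in reports}
    if len(shapes) != 1:
        raise ShapeError(f"inconsistent class counts across reports: {shapes}")
    acc = np.array([r.accuracy for r in reports])
    confusion = np.sum([r.confusion for r in reports], axis=0)
    return ExperimentResult(
        reports=list(reports),
        mean=float(acc.mean()),
        std=float(acc.std()),
        max=float(acc.max()),
        min=float(acc.min()),
        confusion=confusion,
    )
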