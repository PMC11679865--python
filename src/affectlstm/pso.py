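"""Particle swarm search over the five model hyperparameters.

Velocity update: v' = w v + c1 r1 (p - x) + c2 r2 (g - x), with fresh
uniform[0,1] draws r1, r2 per dimension per call, clipped to +/- the
dimension's range; position update x' = x + v', clamped to the bounds.
Integer dimensions (unit counts, batch size) are searched in continuous
space and rounded only when a position is decoded for evaluation, keeping
the update rules exact.  Updates are synchronous: all fitnesses are
evaluated, then personal and global bests are refreshed once per iteration,
so the global-best loss trace is non-increasing by construction.

Fitness evaluations are cached on the decoded (rounded) hyperparameters so
re-visiting an identical configuration never re-trains a model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import OptimizationError

#: Search bounds: unit counts 1-200, dropout 0.1-0.9, batch size 1-128.
DEFAULT_BOUNDS = [
    ("units1", 1, 200, "integer"),
    ("units2", 1, 200, "integer"),
    ("dense_units", 1, 200, "integer"),
    ("dropout_rate", 0.1, 0.9, "continuous"),
    ("batch_size", 1, 128, "integer"),
]


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    kind: str  # 'integer' | 'continuous'

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.kind not in ("integer", "continuous"):
            raise ValueError(f"{self.name}: kind must be integer or continuous")

    @property
    def range(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class SearchSpace:
    dims: tuple[Dimension, ...]

    @classmethod
    def default(cls) -> "SearchSpace":
        return cls(tuple(Dimension(*d) for d in DEFAULT_BOUNDS))

    @classmethod
    def desk(cls, max_units: int = 32, batch_lo: int = 16,
             batch_hi: int = 64) -> "SearchSpace":
        """A reduced space for desk-scale experiments on synthetic data."""
        return cls((
            Dimension("units1", 2, max_units, "integer"),
            Dimension("units2", 2, max_units, "integer"),
            Dimension("dense_units", 2, max_units, "integer"),
            Dimension("dropout_rate", 0.1, 0.9, "continuous"),
            Dimension("batch_size", batch_lo, batch_hi, "integer"),
        ))

    def __len__(self) -> int:
        return len(self.dims)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dims], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dims], dtype=float)


@dataclass
class PSOConfig:
    """Swarm settings; the defaults are the reference settings (w=0.2, c1=0.3,
    c2=0.5, 15 particles, 10 iterations)."""

    w: float = 0.2
    c1: float = 0.3
    c2: float = 0.5
    particles: int = 15
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w, self.c1, self.c2) < 0:
            raise ValueError("w, c1, c2 must be non-negative")
        if self.particles < 1 or self.iterations < 1:
            raise ValueError("particles and iterations must be >= 1")


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    best_x: np.ndarray
    best_f: float = math.inf


def update_velocity(
    particle: Particle,
    global_best: np.ndarray,
    config: PSOConfig,
    rng: np.random.Generator,
    space: SearchSpace,
) -> np.ndarray:
    """New velocity from inertia + cognitive + social terms, clipped to
    +/- each dimension's range."""
    dims = len(particle.x)
    r1 = rng.random(dims)
    r2 = rng.random(dims)
    v = (config.w * particle.v
         + config.c1 * r1 * (particle.best_x - particle.x)
         + config.c2 * r2 * (global_best - particle.x))
    vmax = space.upper - space.lower
    return np.clip(v, -vmax, vmax)


def update_position(particle: Particle, new_velocity: np.ndarray,
                    space: SearchSpace) -> np.ndarray:
    """x' = x + v', clamped to the per-dimension bounds."""
    return np.clip(particle.x + new_velocity, space.lower, space.upper)


def decode_position(x: np.ndarray, space: SearchSpace) -> dict[str, float | int]:
    """Round integer dimensions to the nearest whole value, clamp everything
    to the bounds, and name the result."""
    out: dict[str, float | int] = {}
    for value, dim in zip(x, space.dims):
        if dim.kind == "integer":
            v = int(round(value))
            out[dim.name] = int(min(max(v, dim.lower), dim.upper))
        else:
            out[dim.name] = float(min(max(value, dim.lower), dim.upper))
    return out


@dataclass
class EvalRecord:
    iteration: int
    particle: int
    position: np.ndarray
    decoded: dict
    loss: float
    cached: bool


@dataclass
class PSOResult:
    best_params: dict
    best_position: np.ndarray
    best_loss: float
    trace: list[tuple[int, float]]      # (iteration, global best loss)
    log: list[EvalRecord] = field(repr=False, default_factory=list)

    @property
    def fitness_calls(self) -> int:
        return sum(not r.cached for r in self.log)


def optimize(
    fitness: Callable[[dict], float],
    space: SearchSpace,
    config: PSOConfig,
) -> PSOResult:
    """Run the swarm and return the best decoded hyperparameters.

    ``fitness`` receives a decoded hyperparameter dict and returns a loss;
    non-finite returns are recorded as +inf and never become a best.  All
    randomness flows from ``config.seed``, so the full evaluation log is
    reproducible bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    dims = len(space)
    lower, upper = space.lower, space.upper
    particles = [
        Particle(
            x=rng.uniform(lower, upper),
            v=rng.uniform(-0.1 * (upper - lower), 0.1 * (upper - lower)),
            best_x=np.zeros(dims),
        )
        for _ in range(config.particles)
    ]
    for p in particles:
        p.best_x = p.x.copy()

    cache: dict[tuple, float] = {}
    log: list[EvalRecord] = []
    g_best_x: np.ndarray | None = None
    g_best_f = math.inf
    trace: list[tuple[int, float]] = []

    for it in range(1, config.iterations + 1):
        for idx, p in enumerate(particles):
            decoded = decode_position(p.x, space)
            key = tuple(sorted(decoded.items()))
            cached = key in cache
            if cached:
                loss = cache[key]
            else:
                loss = fitness(decoded)
                loss = float(loss) if np.isfinite(loss) else math.inf
                cache[key] = loss
            log.append(EvalRecord(it, idx, p.x.copy(), decoded, loss, cached))
            if loss < p.best_f:
                p.best_f = loss
                p.best_x = p.x.copy()
        # synchronous global-best refresh
        for p in particles:
            if p.best_f < g_best_f:
                g_best_f = p.best_f
                g_best_x = p.best_x.copy()
        if g_best_x is None:
            raise OptimizationError(
                "every fitness evaluation in the first iteration was non-finite")
        trace.append((it, g_best_f))
        for p in particles:
            p.v = update_velocity(p, g_best_x, config, rng, space)
            p.x = update_position(p, p.v, space)

    return PSOResult(
        best_params=decode_position(g_best_x, space),
        best_position=g_best_x,
        best_loss=g_best_f,
        trace=trace,
        log=log,
    )


def write_eval_log(log: list[EvalRecord], path) -> None:
    """CSV of every evaluation: iteration, particle, decoded values, loss."""
    import csv

    if not log:
        return
    names = list(log[0].decoded)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "particle", *names, "loss", "cached"])
        for r in log:
            writer.writerow(
                [r.iteration, r.particle, *[r.decoded[n] for n in names],
                 r.loss, int(r.cached)])
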