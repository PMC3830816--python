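"""Particle swarm optimization, plus the LS-SVM hyperparameter tuner.

The swarm maximizes a caller-supplied fitness over a box. Velocities follow
the standard inertia / personal-best / global-best update with fresh uniform
draws per particle per dimension per step; positions are clamped to the box
with the velocity zeroed in any clamped dimension.

For LS-SVM tuning the search runs in (log2 gamma, log2 sigma2) coordinates
over [-4, 12]^2 and the fitness is the mean accuracy of an internal
stratified cross-validation on the node's training data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import lssvm
from .exceptions import FitnessEvaluationError, ValidationError
from .folds import stratified_kfold

logger = logging.getLogger(__name__)

FitnessFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm constants; defaults follow the reference experimental setup."""

    n_particles: int = 25
    inertia: float = 0.75
    c1: float = 2.0
    c2: float = 2.0
    bounds: tuple[tuple[float, float], ...] = ((-4.0, 12.0), (-4.0, 12.0))
    max_iterations: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        if self.inertia < 0:
            raise ValidationError("inertia must be non-negative")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValidationError(f"invalid bounds ({lo}, {hi})")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float


@dataclass
class Swarm:
    particles: list[Particle]
    best_position: np.ndarray
    best_fitness: float
    config: SwarmConfig
    rng: np.random.Generator
    iteration: int = 0
    history: list[float] = field(default_factory=list)


def _evaluate(fitness: FitnessFn, position: np.ndarray) -> float:
    try:
        value = float(fitness(position))
    except Exception as exc:
        raise FitnessEvaluationError(
            f"fitness evaluation failed at position {position.tolist()}: {exc}",
            position=position.copy()) from exc
    if np.isnan(value):
        raise FitnessEvaluationError(
            f"fitness returned NaN at position {position.tolist()}",
            position=position.copy())
    return value


def initialize_swarm(config: SwarmConfig, fitness: FitnessFn) -> Swarm:
    """Seeded uniform initialization over the box; zero velocities."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    particles = []
    for _ in range(config.n_particles):
        pos = rng.uniform(lo, hi)
        value = _evaluate(fitness, pos)
        particles.append(Particle(position=pos, velocity=np.zeros(config.ndim),
                                  best_position=pos.copy(),
                                  best_fitness=value))
    best = max(particles, key=lambda p: p.best_fitness)
    return Swarm(particles=particles, best_position=best.best_position.copy(),
                 best_fitness=best.best_fitness, config=config, rng=rng)


def step(swarm: Swarm, fitness: FitnessFn) -> Swarm:
    """One synchronous swarm update (in place; also returned)."""
    cfg = swarm.config
    lo, hi = cfg.lower, cfg.upper
    vmax = hi - lo
    for p in swarm.particles:
        r1 = swarm.rng.random(cfg.ndim)
        r2 = swarm.rng.random(cfg.ndim)
        p.velocity = (cfg.inertia * p.velocity
                      + cfg.c1 * r1 * (p.best_position - p.position)
                      + cfg.c2 * r2 * (swarm.best_position - p.position))
        np.clip(p.velocity, -vmax, vmax, out=p.velocity)
        p.position = p.position + p.velocity
        clamped = (p.position < lo) | (p.position > hi)
        if clamped.any():
            np.clip(p.position, lo, hi, out=p.position)
            p.velocity[clamped] = 0.0
        value = _evaluate(fitness, p.position)
        if value > p.best_fitness:
            p.best_fitness = value
            p.best_position = p.position.copy()
    best = max(swarm.particles, key=lambda p: p.best_fitness)
    if best.best_fitness > swarm.best_fitness:
        swarm.best_fitness = best.best_fitness
        swarm.best_position = best.best_position.copy()
    swarm.iteration += 1
    return swarm


def optimize(fitness: FitnessFn,
             config: SwarmConfig) -> tuple[np.ndarray, float, list[float]]:
    """Run ``max_iterations`` steps; return (best position, fitness, trace)."""
    swarm = initialize_swarm(config, fitness)
    swarm.history.append(swarm.best_fitness)
    for _ in range(config.max_iterations):
        step(swarm, fitness)
        swarm.history.append(swarm.best_fitness)
    return swarm.best_position.copy(), swarm.best_fitness, list(swarm.history)


def tune_hyperparameters(
    X: np.ndarray,
    y: Sequence[float],
    config: SwarmConfig,
    inner_cv_folds: int = 5,
    scale: bool = True,
) -> tuple[lssvm.Hyperparameters, list[float]]:
    """Pick (gamma, sigma2) for a binary LS-SVM node by PSO.

    Fitness is mean held-out accuracy of a stratified ``inner_cv_folds``-fold
    CV on (X, y), with a vanishingly small penalty on log2(gamma) so exact
    ties resolve toward the simpler (smaller gamma) model. The fold count is
    reduced automatically when the minority class is too small to keep at
    least 2 of its members per fold; with fewer than 4 minority points the
    fitness falls back to training accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    min_count = int(np.bincount((y > 0).astype(int), minlength=2).min())

    k = min(inner_cv_folds, min_count // 2)
    if k < 2:
        warnings.warn("minority class too small for internal CV; "
                      "tuning on training accuracy", stacklevel=2)
        folds = None
    else:
        if k < inner_cv_folds:
            warnings.warn(f"internal CV folds reduced to {k} "
                          f"(minority class has {min_count} points)",
                          stacklevel=2)
        folds = stratified_kfold(y, k, seed=config.seed)

    lo0 = config.lower[0]
    span0 = config.upper[0] - lo0

    def fitness(position: np.ndarray) -> float:
        hyper = lssvm.Hyperparameters(gamma=2.0 ** position[0],
                                      sigma2=2.0 ** position[1])
        if folds is None:
            model = lssvm.fit(X, y, hyper, scale=scale)
            acc = float(np.mean(lssvm.predict(model, X) == y))
        else:
            accs = []
            for f in range(1, folds.k + 1):
                tr, te = folds.train_indices(f), folds.test_indices(f)
                model = lssvm.fit(X[tr], y[tr], hyper, scale=scale)
                accs.append(np.mean(lssvm.predict(model, X[te]) == y[te]))
            acc = float(np.mean(accs))
        # tie-break toward smaller gamma; too small to perturb real ranking
        return acc - 1e-9 * (position[0] - lo0) / span0

    best_position, best_fitness, history = optimize(fitness, config)
    hyper = lssvm.Hyperparameters(gamma=2.0 ** best_position[0],
                                  sigma2=2.0 ** best_position[1])
    logger.info("tuned gamma=%.4g sigma2=%.4g (fitness %.4f)",
                hyper.gamma, hyper.sigma2, best_fitness)
    return hyper, history


def config_from_mapping(mapping: dict) -> SwarmConfig:
    """Build a SwarmConfig from config-file keys (YAML/JSON)."""
    kwargs = {}
    if "n_particles" in mapping:
        kwargs["n_particles"] = int(mapping["n_particles"])
    if "inertia" in mapping:
        kwargs["inertia"] = float(mapping["inertia"])
    if "c1" in mapping:
        kwargs["c1"] = float(mapping["c1"])
    if "c2" in mapping:
        kwargs["c2"] = float(mapping["c2"])
    if "log2_bounds" in mapping:
        kwargs["bounds"] = tuple(
            (float(lo), float(hi)) for lo, hi in mapping["log2_bounds"])
    if "max_iterations" in mapping:
        kwargs["max_iterations"] = int(mapping["max_iterations"])
    if "seed" in mapping:
        kwargs["seed"] = int(mapping["seed"])
    return SwarmConfig(**kwargs)


def with_seed(config: SwarmConfig, seed: int) -> SwarmConfig:
    """A copy of the config with a different seed."""
    return replace(config, seed=seed)
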