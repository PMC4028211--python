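"""GCS-encoding modified binary PSO over the second-level gene pool.

Particles are bit vectors over the N_gn2 pooled genes. Velocities follow the
standard inertia/cognitive/social update; the position rule is binary and
biased by gene importance: each velocity component is modulated by the gene's
relative GCS factor f_j = GCS(j) * N_gn2 / sum_k GCS(k) before it enters the
sigmoid, so that at fixed dynamics the probability a bit turns on is
non-decreasing in GCS and reduces exactly to the unmodulated rule when all
GCS are equal. Fitness is 5-fold cross-validated ELM accuracy minus a small
penalty proportional to subset size, so that among equally accurate subsets
the smaller one wins.

Randomness is drawn from per-(iteration, particle) counter-derived streams so
runs are reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_data import ValidationError
from .elm import kfold_cv_accuracy
from .gene_pools import GeneClustering


@dataclass
class SwarmConfig:
    ns: int = 50  # swarm size
    max_iter: int = 40
    c1: float = 1.6
    c2: float = 1.6
    w_start: float = 1.2
    w_end: float = 0.4
    a: float = 0.5  # mixing parameter of the discrete position rule
    v_max: float = 4.0  # sigmoid is effectively saturated beyond +/-4
    w_acc: float = 1.0
    w_size: float = 0.1
    n_hidden: int | None = None
    k_folds: int = 5
    cv_seed: int = 0
    fitness_threshold: float | None = None  # early stop, disabled by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ns < 2:
            raise ValidationError("swarm size must be >= 2")
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValidationError("acceleration constants must be positive")
        if self.w_start < self.w_end:
            raise ValidationError("inertia must not increase over iterations")
        if not 0.0 < self.a < 1.0:
            raise ValidationError("a must lie in (0, 1)")


@dataclass
class Particle:
    x: np.ndarray  # bool
    v: np.ndarray
    pbest_x: np.ndarray
    pbest_fit: float


@dataclass
class SwarmResult:
    gbest_x: np.ndarray
    gbest_fit: float
    trace: list[float] = field(default_factory=list)  # gbest fitness per iteration
    selected: np.ndarray | None = None  # pool-local indices
    n_evaluations: int = 0


def _stream(seed: int, iteration: int, particle: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(iteration, particle))
    )


def inertia(iteration: int, config: SwarmConfig) -> float:
    """Linear inertia schedule: w(0) = w_start, w(max_iter) = w_end."""
    frac = iteration / config.max_iter if config.max_iter > 0 else 1.0
    return config.w_start + (config.w_end - config.w_start) * frac


def gcs_factor(gcs_pool: np.ndarray) -> np.ndarray:
    """Relative importance factor f_j = GCS(j) * D / sum GCS; mean 1."""
    gcs_pool = np.asarray(gcs_pool, dtype=float)
    total = gcs_pool.sum()
    if total <= 0:
        return np.ones_like(gcs_pool)
    return gcs_pool * gcs_pool.size / total


def fitness(
    x: np.ndarray, X_pool: np.ndarray, y: np.ndarray, config: SwarmConfig
) -> float:
    """w_acc * CV-accuracy - w_size * |x| / N_gn2 (higher is better)."""
    selected = np.flatnonzero(x)
    if selected.size == 0:
        raise ValidationError("fitness requires a non-empty selection")
    acc = kfold_cv_accuracy(
        X_pool, y, selected, n_hidden=config.n_hidden, k=config.k_folds, seed=config.cv_seed
    )
    return config.w_acc * acc - config.w_size * selected.size / x.size


def repair_empty(x: np.ndarray, gcs_pool: np.ndarray) -> np.ndarray:
    """Switch on the highest-GCS gene if nothing is selected."""
    if not x.any():
        x = x.copy()
        x[int(np.argmax(gcs_pool))] = True
    return x


def _cluster_members(clustering: GeneClustering) -> list[np.ndarray]:
    """Per kept cluster: pool-local positions (within the second-level pool)."""
    kept = clustering.kept_gene_indices()
    pos_of = {int(g): i for i, g in enumerate(kept)}
    groups = []
    for c in np.flatnonzero(clustering.cluster_kept):
        members = [pos_of[int(g)] for g in np.flatnonzero(
            (clustering.assignment == c) & clustering.gene_kept)]
        if members:
            groups.append(np.array(members, dtype=int))
    return groups


def initialize_swarm(
    clustering: GeneClustering, gcs_pool: np.ndarray, config: SwarmConfig
) -> list[Particle]:
    """Random Bernoulli(0.5) bits with every kept cluster forced non-empty."""
    D = gcs_pool.size
    if D == 0:
        raise ValidationError("second-level pool is empty")
    groups = _cluster_members(clustering)
    particles = []
    for p in range(config.ns):
        rng = _stream(config.seed, 0, p)
        x = rng.random(D) < 0.5
        for members in groups:
            if not x[members].any():
                x[members[int(np.argmax(gcs_pool[members]))]] = True
        v = rng.uniform(-config.v_max, config.v_max, D)
        particles.append(Particle(x=x, v=v, pbest_x=x.copy(), pbest_fit=-np.inf))
    return particles


def velocity_update(
    particle: Particle,
    gbest_x: np.ndarray,
    iteration: int,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inertia + cognitive + social update with per-dimension random factors."""
    w = inertia(iteration, config)
    x = particle.x.astype(float)
    r1 = rng.random(x.size)
    r2 = rng.random(x.size)
    v = (
        w * particle.v
        + config.c1 * r1 * (particle.pbest_x.astype(float) - x)
        + config.c2 * r2 * (gbest_x.astype(float) - x)
    )
    return np.clip(v, -config.v_max, config.v_max)


def position_update(
    particle: Particle,
    gbest_x: np.ndarray,
    gcs_pool: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
    v_new: np.ndarray,
) -> np.ndarray:
    """GCS-biased discrete position rule.

    The velocity is modulated per dimension by the relative GCS factor f_j —
    amplified when it pushes toward selection (v >= 0), damped when it pushes
    away (v < 0) — then with probability ``a`` the bit is resampled from the
    sigmoid of the modulated velocity, otherwise it is copied from pbest or
    gbest with equal probability.
    """
    f = gcs_factor(gcs_pool)
    with np.errstate(divide="ignore"):
        v_mod = np.where(v_new >= 0, v_new * f, np.divide(
            v_new, f, out=np.full_like(v_new, -np.inf), where=f > 0))
    resample = rng.random(v_new.size) < config.a
    sig_draw = rng.random(v_new.size) < expit(v_mod)
    from_pbest = rng.random(v_new.size) < 0.5
    copied = np.where(from_pbest, particle.pbest_x, gbest_x)
    x_new = np.where(resample, sig_draw, copied).astype(bool)
    return repair_empty(x_new, gcs_pool)


def run(
    X_pool: np.ndarray,
    y: np.ndarray,
    clustering: GeneClustering,
    gcs_pool: np.ndarray,
    config: SwarmConfig,
) -> SwarmResult:
    """Full swarm search over the second-level pool.

    ``X_pool`` is samples x N_gn2 (training samples, second-level pool genes
    only); ``gcs_pool`` the matching GCS values. Identical subsets are
    memoized — fitness is deterministic given the CV seed. Returns the global
    best with its per-iteration fitness trace (non-decreasing by
    construction).
    """
    gcs_pool = np.asarray(gcs_pool, dtype=float)
    particles = initialize_swarm(clustering, gcs_pool, config)
    cache: dict[bytes, float] = {}
    n_eval = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_eval
        key = np.packbits(x).tobytes()
        if key not in cache:
            cache[key] = fitness(x, X_pool, y, config)
            n_eval += 1
        return cache[key]

    gbest_x, gbest_fit = None, -np.inf
    for p in particles:
        fit = evaluate(p.x)
        p.pbest_fit = fit
        if fit > gbest_fit:
            gbest_x, gbest_fit = p.x.copy(), fit
    trace = [gbest_fit]

    for t in range(config.max_iter):
        for pi, p in enumerate(particles):
            rng = _stream(config.seed, t + 1, pi)
            v_new = velocity_update(p, gbest_x, t, config, rng)
            x_new = position_update(p, gbest_x, gcs_pool, config, rng, v_new)
            p.v = v_new
            p.x = x_new
            fit = evaluate(x_new)
            if fit > p.pbest_fit:
                p.pbest_fit = fit
                p.pbest_x = x_new.copy()
            if fit > gbest_fit:
                gbest_fit = fit
                gbest_x = x_new.copy()
        trace.append(gbest_fit)
        if config.fitness_threshold is not None and gbest_fit >= config.fitness_threshold:
            break

    return SwarmResult(
        gbest_x=gbest_x,
        gbest_fit=float(gbest_fit),
        trace=trace,
        selected=np.flatnonzero(gbest_x),
        n_evaluations=n_eval,
    )
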