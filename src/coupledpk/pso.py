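"""Bounded global-best particle swarm optimisation.

A deliberately small, fully seeded PSO with the standard constriction
settings (inertia 0.729, cognitive = social = 1.494) and clamp-to-bound
constraint handling.  The objective is evaluated on the whole swarm at once
(``func`` receives an (S, d) array and returns (S,) values), which lets
callers batch expensive simulations.  Identical seeds give bit-identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PSOConfig", "PSOResult", "minimize_pso"]


@dataclass(frozen=True)
class PSOConfig:
    """Hyperparameters of the swarm search.

    ``seed`` is mandatory: every stochastic routine in the package threads an
    explicit seed.  ``patience``/``tol`` implement early stopping: the search
    halts once the best objective has not improved by more than ``tol``
    (absolute) for ``patience`` consecutive iterations.
    """

    n_particles: int = 50
    max_iter: int = 500
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    seed: int = 0
    tol: float = 1e-12
    patience: int = 60

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("swarm needs at least 2 particles")
        if self.cognitive <= 0 or self.social <= 0:
            raise ValueError("cognitive and social coefficients must be positive")


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    n_iter: int
    converged: bool
    history: list[float] = field(default_factory=list)


def minimize_pso(func, lower, upper, config: PSOConfig,
                 initial_points: np.ndarray | None = None) -> PSOResult:
    """Minimise ``func`` over the box [lower, upper].

    Parameters
    ----------
    func : callable mapping an (S, d) position array to (S,) objective values.
    lower, upper : box bounds, shape (d,), all finite with lower < upper.
    initial_points : optional extra starting positions (k, d) injected into the
        initial swarm (e.g. the all-zero interaction vector, which is always
        feasible); they replace the first k random particles.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or lower.ndim != 1:
        raise ValueError("lower and upper must be matching 1-D arrays")
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValueError("PSO needs a finite search box")
    if np.any(lower >= upper):
        raise ValueError("each lower bound must be strictly below its upper bound")
    d = lower.size
    rng = np.random.default_rng(config.seed)
    span = upper - lower

    pos = lower + rng.uniform(size=(config.n_particles, d)) * span
    if initial_points is not None:
        pts = np.atleast_2d(np.asarray(initial_points, dtype=float))
        if np.any(pts < lower) or np.any(pts > upper):
            raise ValueError("initial_points must lie inside the bounds")
        k = min(pts.shape[0], config.n_particles)
        pos[:k] = pts[:k]
    vel = np.zeros_like(pos)
    vmax = 0.5 * span

    fitness = np.asarray(func(pos), dtype=float)
    fitness = np.where(np.isfinite(fitness), fitness, np.inf)
    pbest, pbest_f = pos.copy(), fitness.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    history = [gbest_f]
    stall = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        r1 = rng.uniform(size=(config.n_particles, d))
        r2 = rng.uniform(size=(config.n_particles, d))
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest - pos))
        np.clip(vel, -vmax, vmax, out=vel)
        pos = pos + vel
        # clamp to the box and kill the offending velocity component
        low_hit = pos < lower
        high_hit = pos > upper
        pos = np.where(low_hit, lower, np.where(high_hit, upper, pos))
        vel = np.where(low_hit | high_hit, 0.0, vel)

        fitness = np.asarray(func(pos), dtype=float)
        fitness = np.where(np.isfinite(fitness), fitness, np.inf)
        improved = fitness < pbest_f
        pbest[improved] = pos[improved]
        pbest_f[improved] = fitness[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f - config.tol:
            stall = 0
        else:
            stall += 1
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        history.append(gbest_f)
        if stall >= config.patience:
            break
    return PSOResult(x=gbest, fun=gbest_f, n_iter=it,
                     converged=stall >= config.patience, history=history)
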