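"""Plain global-best particle swarm optimisation over a box.

Standard velocity/position updates with inertia ``omega`` and
cognitive/social accelerations ``c1``/``c2`` (constriction-style defaults
0.729 / 1.49445 / 1.49445), velocities clamped to a fraction of each box
side, positions clipped to the box. Fully deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    history: list[float]
    n_evaluations: int


def pso_minimize(
    fun: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    n_particles: int = 20,
    n_iter: int = 50,
    seed: int = 0,
    omega: float = 0.729,
    c1: float = 1.49445,
    c2: float = 1.49445,
    vmax_frac: float = 0.5,
) -> PSOResult:
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or not np.isfinite(bounds).all():
        raise ValueError("bounds must be a finite (k, 2) array")
    if n_particles < 1 or n_iter < 0:
        raise ValueError("need n_particles >= 1 and n_iter >= 0")
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(seed)
    x = lo + rng.random((n_particles, len(lo))) * span
    x0 = x.copy()
    v = (rng.random((n_particles, len(lo))) - 0.5) * 0.2 * span
    vmax = vmax_frac * span

    f = np.array([fun(p) for p in x])
    n_eval = n_particles
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])
    history = [gbest_f]

    for _ in range(n_iter):
        r1 = rng.random((n_particles, len(lo)))
        r2 = rng.random((n_particles, len(lo)))
        v = omega * v + c1 * r1 * (pbest_x - x) + c2 * r2 * (gbest_x - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        f = np.array([fun(p) for p in x])
        n_eval += n_particles
        better = f < pbest_f
        pbest_x[better], pbest_f[better] = x[better], f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        history.append(gbest_f)

    if n_iter == 0 and n_particles == 1:
        # degenerate budget: the (seeded) initial position is the answer
        gbest_x, gbest_f = x0[0], float(f[0])
    return PSOResult(x=gbest_x, fun=gbest_f, history=history, n_evaluations=n_eval)
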