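"""Quantum-behaved particle swarm optimization with Lévy-flight perturbation.

QPSO describes each particle by a wave function rather than a
position/velocity pair: a particle's next position is sampled around an
attractor interpolated between its personal best and the global best, with
a spread proportional to its distance from the swarm's mean best position
("mbest") scaled by the contraction-expansion coefficient beta, which
decays over the run (1.0 -> 0.5 by default).  A Lévy-flight perturbation —
heavy-tailed steps generated by the Mantegna algorithm with stability index
1.5 — is applied with probability 1/L per particle per iteration, scaled by
lam, to help the swarm hop out of local minima.

The optimizer is a generic bound-constrained minimizer: it only needs an
objective callable, so any swarm variant honouring the same contract can
replace it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QPSO", "QPSOResult"]


@dataclass
class QPSOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness per iteration (non-increasing)
    n_evaluations: int


def _levy_steps(rng: np.random.Generator, shape, exponent: float) -> np.ndarray:
    """Mantegna's algorithm for symmetric Lévy-stable steps."""
    from math import gamma, sin, pi

    beta = exponent
    sigma_u = (
        gamma(1 + beta) * sin(pi * beta / 2)
        / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
    ) ** (1 / beta)
    u = rng.normal(0, sigma_u, size=shape)
    v = rng.normal(0, 1, size=shape)
    return u / np.abs(v) ** (1 / beta)


class QPSO:
    """Bound-constrained minimizer.

    Parameters
    ----------
    objective : callable(position) -> float
        Function to minimize (lower is better).
    bounds : (lo, hi) arrays of length d
        Box constraints; out-of-bounds positions are clipped.
    n_particles, n_iterations : swarm size and budget.
    lam : float, default=1.0
        Lévy step scale.
    L : int, default=10
        A particle is Lévy-perturbed with probability 1/L per iteration.
    beta_start, beta_end : contraction-expansion schedule.
    levy_exponent : float, default=1.5
        Stability index of the Lévy steps.
    seed : int
    callback : optional callable(iteration, best_fitness).
    """

    def __init__(
        self,
        objective,
        bounds,
        n_particles: int = 30,
        n_iterations: int = 1000,
        lam: float = 1.0,
        L: int = 10,
        beta_start: float = 1.0,
        beta_end: float = 0.5,
        levy_exponent: float = 1.5,
        levy_enabled: bool = True,
        seed: int = 0,
        callback=None,
    ):
        if n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        self.objective = objective
        self.lo = np.asarray(bounds[0], dtype=float)
        self.hi = np.asarray(bounds[1], dtype=float)
        if self.lo.shape != self.hi.shape or np.any(self.lo >= self.hi):
            raise ValueError("invalid bounds")
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.lam = lam
        self.L = L
        self.beta_start = beta_start
        self.beta_end = beta_end
        self.levy_exponent = levy_exponent
        self.levy_enabled = levy_enabled
        self.seed = seed
        self.callback = callback

    def run(self) -> QPSOResult:
        rng = np.random.default_rng(self.seed)
        d = len(self.lo)
        m = self.n_particles
        X = rng.uniform(self.lo, self.hi, size=(m, d))
        fitness = np.array([self.objective(x) for x in X])
        n_eval = m
        pbest = X.copy()
        pbest_f = fitness.copy()
        g = int(np.argmin(pbest_f))
        gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        history = []

        for it in range(self.n_iterations):
            frac = it / max(self.n_iterations - 1, 1)
            beta = self.beta_start + (self.beta_end - self.beta_start) * frac
            mbest = pbest.mean(axis=0)
            phi = rng.uniform(size=(m, d))
            attractor = phi * pbest + (1 - phi) * gbest
            u = rng.uniform(1e-12, 1.0, size=(m, d))
            sign = np.where(rng.uniform(size=(m, d)) < 0.5, -1.0, 1.0)
            X = attractor + sign * beta * np.abs(mbest - X) * np.log(1.0 / u)
            if self.levy_enabled:
                hop = rng.uniform(size=m) < 1.0 / self.L
                if hop.any():
                    steps = _levy_steps(rng, (int(hop.sum()), d), self.levy_exponent)
                    X[hop] = X[hop] + self.lam * 0.1 * steps * (self.hi - self.lo)
            X = np.clip(X, self.lo, self.hi)

            fitness = np.array([self.objective(x) for x in X])
            n_eval += m
            improved = fitness < pbest_f
            pbest[improved] = X[improved]
            pbest_f[improved] = fitness[improved]
            g = int(np.argmin(pbest_f))
            if pbest_f[g] < gbest_f:
                gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
            history.append(gbest_f)
            if self.callback is not None:
                self.callback(it, gbest_f)

        return QPSOResult(gbest, gbest_f, np.asarray(history), n_eval)
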