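"""Joint selection of descriptors and RBF hyperparameters by swarm search.

Search space encoding.  A candidate is a real vector of length 2 + B where
B = ceil(n_descriptors / 10).  The first two dimensions are the RBF
hyperparameters (mse_goal epsilon, spread delta), clipped to their bounds
(default [1e-4, 5] each).  Each remaining dimension encodes a block of ten
descriptors: the value is clipped to [0, 1023], rounded half-away-from-zero
to an integer and expanded to ten bits, where bit b (1-based from the
least-significant end) selects descriptor (block-1)*10 + b.  E.g. block
value 563 = '1000110011' selects within-block positions {1, 2, 5, 6, 10}.

Fitness.  For a decoded candidate the RBF network is fitted on the masked
training descriptors; the fitness is 1 / (R^2 * R^2_cv10) (lower is
better), balancing fit and robustness, with non-positive metrics floored
at 1e-4 and an additive penalty when the over-fit constraint
0 < R^2 - R^2_cv10 < 0.3 is violated.  The 10-fold partition is fixed per
run so fitness values are comparable across candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

import warnings

from .qpso import QPSO
from .rbf import RBFNetRegressor, TrainingStallWarning
from .validation import cv10, fit_metrics, make_folds

__all__ = [
    "decode",
    "encode_mask",
    "block_selection",
    "fitness",
    "FitnessRecord",
    "OptimizerConfig",
    "JointRBFSelector",
    "joint_optimize",
]

METRIC_FLOOR = 1e-4
DEFAULT_PENALTY = 1e6


def block_selection(value: int, block_size: int = 10) -> list:
    """1-based within-block positions selected by an integer block value
    (LSB-first convention)."""
    if not 0 <= value <= 2**block_size - 1:
        raise ValueError(f"block value {value} outside [0, {2**block_size - 1}]")
    return [b for b in range(1, block_size + 1) if (value >> (b - 1)) & 1]


def decode(
    position,
    n_descriptors: int,
    block_size: int = 10,
    eps_bounds: tuple = (1e-4, 5.0),
    delta_bounds: tuple = (1e-4, 5.0),
) -> tuple[float, float, np.ndarray]:
    """Decode a real position vector into (epsilon, delta, descriptor mask).

    Block values are clipped to [0, 2^block_size - 1] and rounded
    half-away-from-zero; bits addressing indices beyond n_descriptors are
    ignored.
    """
    position = np.asarray(position, dtype=float)
    n_blocks = -(-n_descriptors // block_size)
    if len(position) != 2 + n_blocks:
        raise ValueError(
            f"position length {len(position)} != 2 + {n_blocks} blocks"
        )
    eps = float(np.clip(position[0], *eps_bounds))
    delta = float(np.clip(position[1], *delta_bounds))
    mask = np.zeros(n_descriptors, dtype=bool)
    vmax = 2**block_size - 1
    for blk, raw in enumerate(position[2:]):
        v = int(np.floor(np.clip(raw, 0, vmax) + 0.5))  # half-away-from-zero (values >= 0)
        v = min(v, vmax)
        for b in block_selection(v, block_size):
            idx = blk * block_size + b - 1
            if idx < n_descriptors:
                mask[idx] = True
    return eps, delta, mask


def encode_mask(mask, block_size: int = 10) -> np.ndarray:
    """Integer block values whose decode reproduces the mask (round-trip
    inverse of the block part of :func:`decode`)."""
    mask = np.asarray(mask, dtype=bool)
    n_blocks = -(-len(mask) // block_size)
    values = np.zeros(n_blocks, dtype=int)
    for j in np.flatnonzero(mask):
        blk, b = divmod(j, block_size)
        values[blk] |= 1 << b
    return values


@dataclass
class FitnessRecord:
    fitness: float
    r2: float
    r2_cv10: float
    feasible: bool
    eps: float = np.nan
    delta: float = np.nan
    n_selected: int = 0


def fitness(
    X_train,
    y_train,
    eps: float,
    delta: float,
    mask,
    folds=None,
    cv_folds: int = 10,
    max_neurons: int = 500,
    seed: int = 0,
    gap_limit: float = 0.3,
    penalty: float = DEFAULT_PENALTY,
    form: str = "product",
    basis: str = "halfwidth",
) -> FitnessRecord:
    """Evaluate one candidate.  Empty masks return the worst fitness rather
    than raising."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        worst = 1.0 / (METRIC_FLOOR * METRIC_FLOOR) + penalty
        return FitnessRecord(worst, 0.0, 0.0, False, eps, delta, 0)
    X = np.ascontiguousarray(np.asarray(X_train, dtype=float)[:, mask])
    y = np.asarray(y_train, dtype=float)
    # the swarm explores degenerate corners (tiny mse_goal, huge spread) by
    # design; stalled greedy fits are expected there, not worth a warning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TrainingStallWarning)
        model = RBFNetRegressor(mse_goal=eps, spread=delta, max_neurons=max_neurons, basis=basis)
        model.fit(X, y)
        r2 = fit_metrics(y, model.predict(X))
        if folds is None:
            folds = make_folds(len(y), cv_folds, seed)
        r2cv, _ = cv10(X, y, eps, delta, max_neurons, folds=folds, basis=basis)
    gap = r2 - r2cv
    feasible = (r2 > 0) and (r2cv > 0) and (0 < gap < gap_limit)
    r2f = max(r2, METRIC_FLOOR)
    r2cvf = max(r2cv, METRIC_FLOOR)
    if form == "product":
        base = 1.0 / (r2f * r2cvf)
    elif form == "sum":
        base = 1.0 / r2f + 1.0 / r2cvf
    else:
        raise ValueError(f"unknown fitness form {form!r}")
    value = base if feasible else base + penalty
    return FitnessRecord(value, r2, r2cv, feasible, eps, delta, int(mask.sum()))


@dataclass
class OptimizerConfig:
    population: int = 30
    iterations: int = 1000
    lam: float = 1.0
    L: int = 10
    seed: int = 0
    eps_bounds: tuple = (1e-4, 5.0)
    delta_bounds: tuple = (1e-4, 5.0)
    block_size: int = 10
    cv_folds: int = 10
    max_neurons: int = 500
    gap_limit: float = 0.3
    penalty: float = DEFAULT_PENALTY
    fitness_form: str = "product"
    basis: str = "halfwidth"
    levy_enabled: bool = True


class JointRBFSelector(RegressorMixin, BaseEstimator):
    """Swarm-based joint optimizer of descriptor subset and (epsilon, delta).

    ``fit`` runs the QPSO swarm over the block encoding against the
    training data, keeps the best *feasible* candidate ever evaluated
    (satisfying the over-fit constraint), and refits the final RBF model on
    its descriptor subset.

    Attributes
    ----------
    support_ : int indices of selected descriptors
    mask_ : boolean selection mask
    eps_, delta_ : selected hyperparameters
    model_ : the refitted :class:`RBFNetRegressor`
    record_ : :class:`FitnessRecord` of the winning candidate
    fitness_history_ : best-so-far fitness per iteration (non-increasing)
    """

    def __init__(
        self,
        population: int = 30,
        iterations: int = 1000,
        lam: float = 1.0,
        L: int = 10,
        eps_bounds: tuple = (1e-4, 5.0),
        delta_bounds: tuple = (1e-4, 5.0),
        block_size: int = 10,
        cv_folds: int = 10,
        max_neurons: int = 500,
        gap_limit: float = 0.3,
        penalty: float = DEFAULT_PENALTY,
        fitness_form: str = "product",
        basis: str = "halfwidth",
        levy_enabled: bool = True,
        seed: int = 0,
    ):
        self.population = population
        self.iterations = iterations
        self.lam = lam
        self.L = L
        self.eps_bounds = eps_bounds
        self.delta_bounds = delta_bounds
        self.block_size = block_size
        self.cv_folds = cv_folds
        self.max_neurons = max_neurons
        self.gap_limit = gap_limit
        self.penalty = penalty
        self.fitness_form = fitness_form
        self.basis = basis
        self.levy_enabled = levy_enabled
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        p = X.shape[1]
        n_blocks = -(-p // self.block_size)
        vmax = 2**self.block_size - 1
        lo = np.concatenate([[self.eps_bounds[0], self.delta_bounds[0]], np.zeros(n_blocks)])
        hi = np.concatenate([[self.eps_bounds[1], self.delta_bounds[1]], np.full(n_blocks, vmax)])

        # one fixed CV partition for the whole run: fitness comparable
        folds = make_folds(len(y), self.cv_folds, self.seed)

        best = {"record": None, "mask": None}
        cache: dict = {}

        def objective(pos):
            eps, delta, mask = decode(
                pos, p, self.block_size, self.eps_bounds, self.delta_bounds
            )
            key = (round(eps, 12), round(delta, 12), mask.tobytes())
            rec = cache.get(key)
            if rec is None:
                rec = fitness(
                    X, y, eps, delta, mask,
                    folds=folds,
                    max_neurons=self.max_neurons,
                    gap_limit=self.gap_limit,
                    penalty=self.penalty,
                    form=self.fitness_form,
                    basis=self.basis,
                )
                cache[key] = rec
            if rec.feasible and (
                best["record"] is None or rec.fitness < best["record"].fitness
            ):
                best["record"] = rec
                best["mask"] = mask.copy()
            return rec.fitness

        result = QPSO(
            objective,
            (lo, hi),
            n_particles=self.population,
            n_iterations=self.iterations,
            lam=self.lam,
            L=self.L,
            levy_enabled=self.levy_enabled,
            seed=self.seed,
        ).run()

        if best["record"] is None:
            raise RuntimeError(
                "no feasible candidate found: the over-fit constraint "
                f"0 < R^2 - R^2_cv10 < {self.gap_limit} was never satisfied"
            )
        rec, mask = best["record"], best["mask"]
        self.mask_ = mask
        self.support_ = np.flatnonzero(mask)
        self.eps_ = rec.eps
        self.delta_ = rec.delta
        self.record_ = rec
        self.fitness_history_ = result.history
        self.n_evaluations_ = result.n_evaluations
        self.model_ = RBFNetRegressor(
            mse_goal=rec.eps, spread=rec.delta,
            max_neurons=self.max_neurons, basis=self.basis,
        ).fit(X[:, mask], y)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.predict(X[:, self.mask_])


def joint_optimize(table, config: OptimizerConfig | None = None):
    """Run the joint optimizer on a (training) descriptor table.

    Returns (fitted RBF model, boolean mask, fitness history)."""
    config = config or OptimizerConfig()
    sel = JointRBFSelector(
        population=config.population,
        iterations=config.iterations,
        lam=config.lam,
        L=config.L,
        eps_bounds=config.eps_bounds,
        delta_bounds=config.delta_bounds,
        block_size=config.block_size,
        cv_folds=config.cv_folds,
        max_neurons=config.max_neurons,
        gap_limit=config.gap_limit,
        penalty=config.penalty,
        fitness_form=config.fitness_form,
        basis=config.basis,
        levy_enabled=config.levy_enabled,
        seed=config.seed,
    ).fit(table.X, table.y)
    return sel.model_, sel.mask_, sel.fitness_history_
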