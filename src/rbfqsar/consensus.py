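"""Consensus (averaging) ensembles of RBF sub-models.

The consensus prediction is the unweighted arithmetic mean of the
sub-model predictions, each sub-model evaluated on its own descriptor
subset.  Sub-model selection offers four methods: A, B and C search for
the sub-model subset maximizing the consensus R^2_cv10, R^2 or
R^2 * R^2_cv10 respectively — computed on training data only, the external
validation set is never consulted — and D simply takes the whole pool (the
most stable choice).  A stability sweep scores random N-subsets for each
ensemble size N, yielding boxplot-ready distributions.

Consensus R^2_cv10 is computed by averaging the sub-models' out-of-fold
prediction vectors under one shared fold partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .qpso import QPSO
from .validation import cv10, fit_metrics, make_folds

__all__ = [
    "ConsensusModel",
    "SubmodelPool",
    "build_pool",
    "predict_consensus",
    "select_submodels",
    "stability_sweep",
]


@dataclass
class ConsensusModel:
    """Fitted sub-models with their descriptor masks."""

    submodels: list  # list of (RBFNetRegressor, boolean mask over descriptors)

    @property
    def N(self) -> int:
        return len(self.submodels)

    @property
    def usage_counts(self) -> np.ndarray:
        """n_j: number of sub-models using descriptor j."""
        masks = np.array([np.asarray(m, dtype=bool) for _, m in self.submodels])
        return masks.sum(axis=0)

    @property
    def union_size(self) -> int:
        """s: size of the union descriptor set."""
        return int((self.usage_counts > 0).sum())

    @property
    def union_mask(self) -> np.ndarray:
        return self.usage_counts > 0

    def predict(self, X) -> np.ndarray:
        if self.N == 0:
            raise ValueError("consensus model has no sub-models")
        X = np.asarray(X, dtype=float)
        preds = [model.predict(X[:, np.asarray(mask, dtype=bool)]) for model, mask in self.submodels]
        return np.mean(preds, axis=0)


def predict_consensus(cm: ConsensusModel, X_query) -> np.ndarray:
    """Unweighted mean of sub-model predictions."""
    return cm.predict(X_query)


@dataclass
class SubmodelPool:
    """Pool of fitted sub-models with cached prediction vectors, so that
    subset metrics reduce to row means."""

    entries: list                       # (model, mask, eps, delta)
    train_pred: np.ndarray              # N x n_train
    oof_pred: np.ndarray                # N x n_train (shared fold partition)
    valid_pred: np.ndarray | None       # N x n_valid
    y_train: np.ndarray
    y_valid: np.ndarray | None

    @property
    def size(self) -> int:
        return len(self.entries)

    def metrics(self, subset) -> dict:
        """Consensus metrics for a subset of pool indices."""
        subset = np.asarray(list(subset), dtype=int)
        yhat = self.train_pred[subset].mean(axis=0)
        oof = self.oof_pred[subset].mean(axis=0)
        out = {
            "r2": fit_metrics(self.y_train, yhat),
            "r2_cv10": fit_metrics(self.y_train, oof),
        }
        if self.valid_pred is not None:
            vhat = self.valid_pred[subset].mean(axis=0)
            out["r2_ext"] = fit_metrics(self.y_valid, vhat)
            out["q2_ext"] = fit_metrics(
                self.y_valid, vhat, centering="train_mean",
                train_mean=self.y_train.mean(),
            )
        return out

    def consensus(self, subset=None) -> ConsensusModel:
        subset = range(self.size) if subset is None else subset
        return ConsensusModel([(self.entries[i][0], self.entries[i][1]) for i in subset])


def build_pool(
    fitted,
    X_train,
    y_train,
    X_valid=None,
    y_valid=None,
    cv_seed: int = 0,
    cv_folds: int = 10,
    max_neurons: int = 500,
    basis: str = "halfwidth",
) -> SubmodelPool:
    """Cache train/out-of-fold/validation predictions for each sub-model.

    ``fitted`` is a list of (model, mask, eps, delta); out-of-fold vectors
    are recomputed per sub-model under one shared fold partition.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    folds = make_folds(len(y_train), cv_folds, cv_seed)
    train_preds, oof_preds, valid_preds = [], [], []
    for model, mask, eps, delta in fitted:
        mask = np.asarray(mask, dtype=bool)
        Xm = X_train[:, mask]
        train_preds.append(model.predict(Xm))
        _, oof = cv10(Xm, y_train, eps, delta, max_neurons, folds=folds, basis=basis)
        oof_preds.append(oof)
        if X_valid is not None:
            valid_preds.append(model.predict(np.asarray(X_valid, dtype=float)[:, mask]))
    return SubmodelPool(
        entries=[(m, np.asarray(k, dtype=bool), e, d) for m, k, e, d in fitted],
        train_pred=np.asarray(train_preds),
        oof_pred=np.asarray(oof_preds),
        valid_pred=np.asarray(valid_preds) if X_valid is not None else None,
        y_train=y_train,
        y_valid=np.asarray(y_valid, dtype=float) if y_valid is not None else None,
    )


_METHOD_SCORE = {
    "A": lambda m: m["r2_cv10"],
    "B": lambda m: m["r2"],
    "C": lambda m: m["r2"] * m["r2_cv10"],
}


def select_submodels(
    pool: SubmodelPool,
    method: str = "D",
    search_budget: int = 32768,
    seed: int = 0,
) -> tuple[ConsensusModel, list]:
    """Select sub-models by one of the four methods; returns the consensus
    model and the chosen pool indices.

    Methods A/B/C enumerate all non-empty subsets when the pool admits it
    within ``search_budget`` evaluations, otherwise fall back to a swarm
    search over the subset indicator.  Selection uses training-set metrics
    only.
    """
    if pool.size == 0:
        raise ValueError("empty sub-model pool")
    method = method.upper()
    if method == "D":
        idx = list(range(pool.size))
        return pool.consensus(idx), idx
    if method not in _METHOD_SCORE:
        raise ValueError(f"unknown selection method {method!r}; use A, B, C or D")
    score = _METHOD_SCORE[method]

    n = pool.size
    if 2**n - 1 <= search_budget:
        best_idx, best_val = None, -np.inf
        for r in range(1, n + 1):
            for combo in combinations(range(n), r):
                val = score(pool.metrics(combo))
                if val > best_val:
                    best_val, best_idx = val, list(combo)
        return pool.consensus(best_idx), best_idx

    # swarm search over the binary indicator, block-encoded
    from .joint import decode  # local import to avoid cycle at module load

    n_blocks = -(-n // 10)
    lo = np.zeros(2 + n_blocks)
    hi = np.concatenate([[1.0, 1.0], np.full(n_blocks, 1023.0)])

    def objective(pos):
        _, _, mask = decode(pos, n, 10, (0, 1), (0, 1))
        if not mask.any():
            return np.inf
        return -score(pool.metrics(np.flatnonzero(mask)))

    res = QPSO(objective, (lo, hi), n_particles=20,
               n_iterations=max(search_budget // 20, 50), seed=seed).run()
    _, _, mask = decode(res.best_position, n, 10, (0, 1), (0, 1))
    idx = list(np.flatnonzero(mask))
    return pool.consensus(idx), idx


def stability_sweep(
    pool: SubmodelPool,
    N_range=None,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Distributions of consensus metrics over random N-subsets.

    For each ensemble size N, ``reps`` random subsets are scored; returns a
    tidy frame with min/quartiles/max per metric (boxplot-ready)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if N_range is None:
        N_range = range(2, pool.size + 1)
    metric_names = ["r2", "r2_cv10"] + (["q2_ext"] if pool.valid_pred is not None else [])
    rows = []
    for N in N_range:
        if not 1 <= N <= pool.size:
            raise ValueError(f"ensemble size {N} outside [1, {pool.size}]")
        samples = {m: [] for m in metric_names}
        for _ in range(reps):
            subset = rng.choice(pool.size, size=N, replace=False)
            met = pool.metrics(subset)
            for m in metric_names:
                samples[m].append(met[m])
        for m in metric_names:
            vals = np.asarray(samples[m])
            rows.append(
                {
                    "N": N,
                    "metric": m,
                    "min": vals.min(),
                    "q1": np.quantile(vals, 0.25),
                    "median": np.median(vals),
                    "q3": np.quantile(vals, 0.75),
                    "max": vals.max(),
                }
            )
    return pd.DataFrame(rows)
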