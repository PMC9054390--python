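"""Permutation-based descriptor screening under randomized RBF settings.

For each of ``n_param_draws`` random hyperparameter pairs (mse_goal drawn
log-uniformly, spread uniformly) and each of ``n_repeats`` random 90/10
splits of the data, an RBF network is fitted on the 90% block and scored on
the held-out 10% (R0^2).  Each descriptor column of the held-out block is
then shuffled in turn — the model is never refitted — and the drop in
held-out R^2, Ir(i) = R0^2 - R1^2(i), is the descriptor's importance for
that repeat.  The grand mean over all draws and repeats ranks descriptors;
those above a threshold (default 0.01) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

import warnings

from .datatable import DescriptorTable
from .rbf import RBFNetRegressor, TrainingStallWarning
from .validation import fit_metrics

__all__ = ["PermutationScreen", "ImportanceResult", "mdi_importance", "select_by_threshold"]


@dataclass
class ImportanceResult:
    mean_importance: np.ndarray          # Ir-bar per descriptor
    raw_importance: np.ndarray           # (draws*repeats) x descriptors
    retained: list                       # indices with Ir-bar > threshold, descending
    threshold: float
    descriptor_names: list | None = None

    def to_dataframe(self) -> pd.DataFrame:
        p = len(self.mean_importance)
        names = self.descriptor_names or [f"d{j}" for j in range(p)]
        return pd.DataFrame(
            {
                "descriptor": names,
                "mean_Ir": self.mean_importance,
                "sd_Ir": self.raw_importance.std(axis=0, ddof=1)
                if self.raw_importance.shape[0] > 1
                else np.zeros(p),
                "retained": [j in set(self.retained) for j in range(p)],
            }
        )


class PermutationScreen(SelectorMixin, BaseEstimator):
    """Descriptor screen by held-out permutation importance.

    Parameters mirror the screening procedure: ``n_param_draws`` random
    (mse_goal, spread) pairs with mse_goal log-uniform on ``eps_range``
    (default [1e-3, 1e-1]) and spread uniform on ``delta_range`` (default
    [1, 5]); ``n_repeats`` random 90/10 splits per draw; descriptors with
    mean importance strictly above ``threshold`` are retained.
    """

    def __init__(
        self,
        n_repeats: int = 50,
        n_param_draws: int = 100,
        split_fraction: float = 0.9,
        eps_range: tuple = (1e-3, 1e-1),
        delta_range: tuple = (1.0, 5.0),
        max_neurons: int = 500,
        threshold: float = 0.01,
        basis: str = "halfwidth",
        seed: int = 0,
    ):
        self.n_repeats = n_repeats
        self.n_param_draws = n_param_draws
        self.split_fraction = split_fraction
        self.eps_range = eps_range
        self.delta_range = delta_range
        self.max_neurons = max_neurons
        self.threshold = threshold
        self.basis = basis
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        n_hold = n - int(round(self.split_fraction * n))
        if n_hold < 2:
            raise ValueError("held-out block smaller than 2 rows; lower split_fraction")
        rng = np.random.default_rng(self.seed)
        log_lo, log_hi = np.log10(self.eps_range[0]), np.log10(self.eps_range[1])

        raw = np.empty((self.n_param_draws * self.n_repeats, p))
        row = 0
        for _ in range(self.n_param_draws):
            eps = 10.0 ** rng.uniform(log_lo, log_hi)
            delta = rng.uniform(*self.delta_range)
            for _ in range(self.n_repeats):
                perm = rng.permutation(n)
                hold, fitidx = perm[:n_hold], perm[n_hold:]
                with warnings.catch_warnings():
                    # randomly drawn hyperparameters include settings no
                    # single fit could satisfy; stalls are expected
                    warnings.simplefilter("ignore", TrainingStallWarning)
                    model = RBFNetRegressor(
                        mse_goal=eps, spread=delta,
                        max_neurons=self.max_neurons, basis=self.basis,
                    ).fit(X[fitidx], y[fitidx])
                Xb, yb = X[hold], y[hold]
                r0 = fit_metrics(yb, model.predict(Xb))
                for i in range(p):
                    Xs = Xb.copy()
                    Xs[:, i] = rng.permutation(Xs[:, i])
                    raw[row, i] = r0 - fit_metrics(yb, model.predict(Xs))
                row += 1

        self.raw_importance_ = raw
        self.importances_ = raw.mean(axis=0)
        order = np.argsort(-self.importances_)
        self.retained_ = [int(j) for j in order if self.importances_[j] > self.threshold]
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "importances_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.retained_] = True
        return mask

    def result(self, descriptor_names=None) -> ImportanceResult:
        check_is_fitted(self, "importances_")
        return ImportanceResult(
            self.importances_, self.raw_importance_, list(self.retained_),
            self.threshold, descriptor_names,
        )


def mdi_importance(
    table: DescriptorTable,
    split_fraction: float = 0.9,
    n_repeats: int = 50,
    n_param_draws: int = 100,
    eps_range: tuple = (1e-3, 1e-1),
    delta_range: tuple = (1.0, 5.0),
    max_neurons: int = 500,
    threshold: float = 0.01,
    seed: int = 0,
) -> ImportanceResult:
    """Run the permutation screen on a descriptor table."""
    screen = PermutationScreen(
        n_repeats=n_repeats,
        n_param_draws=n_param_draws,
        split_fraction=split_fraction,
        eps_range=eps_range,
        delta_range=delta_range,
        max_neurons=max_neurons,
        threshold=threshold,
        seed=seed,
    ).fit(table.X, table.y)
    return screen.result(table.descriptor_names)


def select_by_threshold(result: ImportanceResult, threshold: float) -> list:
    """Indices with mean importance strictly greater than the threshold,
    ordered by descending importance.  Empty selections return []."""
    if not np.isfinite(threshold) and threshold > 0:
        raise ValueError("threshold must be finite or -inf")
    order = np.argsort(-result.mean_importance)
    return [int(j) for j in order if result.mean_importance[j] > threshold]
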