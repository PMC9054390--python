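"""Self-organizing map clustering on a small node grid.

Batch-trained SOM used for the "cluster first, then classify" data split:
compounds are mapped onto a small grid of nodes (3x3 hexagonal by default)
by competitive learning, and each node's catchment defines one cluster of
structurally similar compounds.  Only the partition is consumed downstream,
not the map geometry.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

__all__ = ["SOMClusterer"]


def _grid_coordinates(n_nodes: int, topology: str) -> np.ndarray:
    """Node positions for an (approximately square) grid."""
    rows = int(np.floor(np.sqrt(n_nodes)))
    while n_nodes % rows:
        rows -= 1
    cols = n_nodes // rows
    rr, cc = np.divmod(np.arange(n_nodes), cols)
    if topology == "hexagonal":
        x = cc + 0.5 * (rr % 2)
        ypos = rr * (np.sqrt(3.0) / 2.0)
    elif topology == "rectangular":
        x, ypos = cc.astype(float), rr.astype(float)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return np.column_stack([x, ypos])


class SOMClusterer(ClusterMixin, BaseEstimator):
    """Batch self-organizing map.

    Parameters
    ----------
    n_nodes : int, default=9
        Number of map nodes (= maximum number of clusters).
    n_iterations : int, default=300
        Batch training epochs.
    topology : {"hexagonal", "rectangular"}, default="hexagonal"
    sigma_start, sigma_end : float
        Neighborhood radius, decayed linearly from start to end over
        training (defaults 3 -> 1, suited to a 3x3 map).
    standardize : bool, default=True
        z-score features before distance computation.
    seed : int, default=0

    Attributes
    ----------
    labels_ : ndarray of int
        1-based best-matching-unit label per sample (in [1, n_nodes]).
    node_weights_ : ndarray of shape (n_nodes, p)
        Codebook vectors (in standardized space when ``standardize``).
    """

    def __init__(
        self,
        n_nodes: int = 9,
        n_iterations: int = 300,
        topology: str = "hexagonal",
        sigma_start: float = 3.0,
        sigma_end: float = 1.0,
        standardize: bool = True,
        seed: int = 0,
    ):
        self.n_nodes = n_nodes
        self.n_iterations = n_iterations
        self.topology = topology
        self.sigma_start = sigma_start
        self.sigma_end = sigma_end
        self.standardize = standardize
        self.seed = seed

    def fit(self, X, y=None):
        X = check_array(X)
        n = X.shape[0]
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_nodes > n:
            raise ValueError(f"n_nodes={self.n_nodes} exceeds n_samples={n}")
        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Z = (X - mu) / sd
            self._mu, self._sd = mu, sd
        else:
            Z = X
            self._mu = self._sd = None

        rng = np.random.default_rng(self.seed)
        grid = _grid_coordinates(self.n_nodes, self.topology)
        grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)

        # initialise codebook on random data points
        W = Z[rng.choice(n, size=self.n_nodes, replace=False)].astype(float)
        for t in range(self.n_iterations):
            frac = t / max(self.n_iterations - 1, 1)
            sigma = self.sigma_start + (self.sigma_end - self.sigma_start) * frac
            d2 = ((Z[:, None, :] - W[None, :, :]) ** 2).sum(-1)
            bmu = np.argmin(d2, axis=1)
            H = np.exp(-grid_d2[:, bmu] / (2.0 * sigma**2))  # (nodes, samples)
            denom = H.sum(axis=1)
            # nodes with empty (near-zero) neighborhood mass keep their weights
            upd = denom > 1e-12
            W[upd] = (H[upd] @ Z) / denom[upd, None]

        d2 = ((Z[:, None, :] - W[None, :, :]) ** 2).sum(-1)
        self.node_weights_ = W
        self.labels_ = np.argmin(d2, axis=1) + 1
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
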