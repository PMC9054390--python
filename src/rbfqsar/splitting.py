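"""Training/validation splitting by SOM clustering plus systematic picking.

The split clusters compounds by structural similarity (SOM), then within
each cluster sorts by ascending endpoint and sends the middle member of
every complete block of five to the validation set.  Both extremes of the
endpoint range stay in training, validation compounds interleave training
ones, and every validation compound has structural neighbours in training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatable import DescriptorTable
from .som import SOMClusterer

__all__ = [
    "SplitResult",
    "DiversityReport",
    "som_cluster",
    "pick_one_in_five",
    "som_split",
    "diversity_diagnostics",
]


@dataclass
class SplitResult:
    train_indices: np.ndarray
    valid_indices: np.ndarray
    cluster_labels: np.ndarray

    def __post_init__(self):
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.valid_indices = np.asarray(self.valid_indices, dtype=int)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
        n = len(self.cluster_labels)
        union = np.sort(np.concatenate([self.train_indices, self.valid_indices]))
        if not np.array_equal(union, np.arange(n)):
            raise ValueError("train and validation indices must partition all rows")

    def to_dataframe(self, compound_ids=None) -> pd.DataFrame:
        n = len(self.cluster_labels)
        role = np.empty(n, dtype=object)
        role[self.train_indices] = "train"
        role[self.valid_indices] = "valid"
        ids = compound_ids if compound_ids is not None else np.arange(n)
        return pd.DataFrame(
            {"compound_id": ids, "cluster": self.cluster_labels, "set": role}
        )


@dataclass
class DiversityReport:
    pc_scores: np.ndarray
    explained_variance_ratio: np.ndarray
    distance_matrix: np.ndarray  # ordered train-block then valid-block, in [0, 1]
    row_order: np.ndarray


def som_cluster(
    table: DescriptorTable,
    n_nodes: int = 9,
    n_iterations: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Assign each compound to its best-matching SOM node (1-based labels)."""
    som = SOMClusterer(n_nodes=n_nodes, n_iterations=n_iterations, seed=seed)
    return som.fit_predict(table.X)


def pick_one_in_five(
    cluster_labels,
    y,
    pick_position: int = 3,
    compound_ids=None,
    seed: int = 0,
) -> SplitResult:
    """Within each cluster, sort ascending by endpoint and pick the
    ``pick_position``-th member of every complete block of five for
    validation; incomplete trailing blocks contribute nothing.

    Ties in y are broken by compound id, so the split is deterministic
    (the ``seed`` argument is accepted for interface uniformity but the
    procedure has no randomness).
    """
    if not 1 <= pick_position <= 5:
        raise ValueError("pick_position must lie in 1..5")
    cluster_labels = np.asarray(cluster_labels)
    y = np.asarray(y, dtype=float)
    n = len(y)
    ids = (
        [str(c) for c in compound_ids]
        if compound_ids is not None
        else [f"{i:09d}" for i in range(n)]
    )
    valid = []
    for lab in np.unique(cluster_labels):
        members = np.flatnonzero(cluster_labels == lab)
        order = sorted(members, key=lambda i: (y[i], ids[i]))
        for start in range(0, len(order) - len(order) % 5, 5):
            valid.append(order[start + pick_position - 1])
    valid = np.sort(np.asarray(valid, dtype=int))
    train = np.setdiff1d(np.arange(n), valid)
    return SplitResult(train, valid, cluster_labels)


def som_split(
    table: DescriptorTable,
    n_nodes: int = 9,
    n_iterations: int = 300,
    pick_position: int = 3,
    seed: int = 0,
) -> SplitResult:
    """Cluster with the SOM, then pick one-in-five per cluster."""
    labels = som_cluster(table, n_nodes=n_nodes, n_iterations=n_iterations, seed=seed)
    return pick_one_in_five(labels, table.y, pick_position, table.compound_ids)


def diversity_diagnostics(
    table: DescriptorTable, split: SplitResult, n_components: int = 2
) -> DiversityReport:
    """Chemical-space diagnostics: PCA scores on standardized descriptors and
    the min-max-normalized pairwise Euclidean distance matrix ordered
    train-block first, validation-block second (plot-ready, not rendered)."""
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    X = table.X
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    n_components = min(n_components, min(Z.shape))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)

    order = np.concatenate([split.train_indices, split.valid_indices])
    Zo = Z[order]
    d2 = ((Zo[:, None, :] - Zo[None, :, :]) ** 2).sum(-1)
    D = np.sqrt(np.maximum(d2, 0.0))
    dmax = D.max()
    if dmax > 0:
        D = D / dmax
    return DiversityReport(scores, pca.explained_variance_ratio_, D, order)
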