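"""Compound x descriptor tables: loading, validation, and pruning.

The pruning step mirrors standard QSAR preprocessing: drop descriptors with
constant or null (all-missing) values, then break up highly correlated
pairs (|Pearson r| above a threshold, 0.85 by default) by keeping the
member more correlated with the endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DescriptorTable", "PruneLog", "load_table", "prune_descriptors"]

logger = logging.getLogger(__name__)


@dataclass
class DescriptorTable:
    """A validated compound x descriptor table with endpoint.

    X holds one row per compound, one column per descriptor; y is the
    endpoint (-log LC50 in mol/L for the toxicity application).  Columns
    that are entirely missing are tolerated (they are removed by
    :func:`prune_descriptors` as "null"); any other missing value is
    rejected at validation.
    """

    compound_ids: list
    X: np.ndarray
    descriptor_names: list
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.validate()

    def validate(self) -> None:
        n, p = self.X.shape
        if len(self.compound_ids) != n or len(self.y) != n:
            raise ValueError("compound_ids, X rows and y must have equal length")
        if len(self.descriptor_names) != p:
            raise ValueError("descriptor_names length must match X columns")
        if len(set(self.descriptor_names)) != p:
            raise ValueError("descriptor names must be unique")
        if np.isnan(self.y).any():
            raise ValueError("endpoint contains missing values")
        # all-NaN columns are allowed (pruned later as "null")
        partial_nan = [
            name
            for j, name in enumerate(self.descriptor_names)
            if np.isnan(self.X[:, j]).any() and not np.isnan(self.X[:, j]).all()
        ]
        if partial_nan:
            raise ValueError(f"descriptors with partial missing values: {partial_nan[:5]}")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, indices) -> "DescriptorTable":
        indices = np.asarray(indices, dtype=int)
        return DescriptorTable(
            [self.compound_ids[i] for i in indices],
            self.X[indices],
            list(self.descriptor_names),
            self.y[indices],
        )

    def subset_columns(self, indices) -> "DescriptorTable":
        indices = np.asarray(indices, dtype=int)
        return DescriptorTable(
            list(self.compound_ids),
            self.X[:, indices],
            [self.descriptor_names[j] for j in indices],
            self.y.copy(),
        )

    def to_dataframe(self, endpoint_column="endpoint", id_column="compound_id") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.descriptor_names)
        df.insert(0, id_column, self.compound_ids)
        df[endpoint_column] = self.y
        return df


@dataclass
class PruneLog:
    """Record of every descriptor removal: name, reason and the correlated
    partner that caused it (for correlation removals)."""

    entries: list = field(default_factory=list)

    def add(self, descriptor: str, reason: str, partner: str = "", r: float = np.nan):
        self.entries.append(
            {"descriptor": descriptor, "reason": reason, "partner": partner, "r": r}
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["descriptor", "reason", "partner", "r"])

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def load_table(path, endpoint_column: str, id_column: str, sep=None) -> DescriptorTable:
    """Load a delimited compound x descriptor table.

    Rows with any non-numeric or missing descriptor or endpoint value are
    dropped (and the count logged); columns that are *entirely* missing are
    kept and left to :func:`prune_descriptors`.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (endpoint_column, id_column):
        if col not in df.columns:
            raise KeyError(f"required column {col!r} not found in {path}")
    desc_cols = [c for c in df.columns if c not in (endpoint_column, id_column)]
    if not desc_cols:
        raise ValueError("no descriptor columns found")
    numeric = df[desc_cols].apply(pd.to_numeric, errors="coerce")
    y = pd.to_numeric(df[endpoint_column], errors="coerce")

    all_nan_cols = [c for c in desc_cols if numeric[c].isna().all()]
    check_cols = [c for c in desc_cols if c not in all_nan_cols]
    keep = ~(numeric[check_cols].isna().any(axis=1) | y.isna())
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("load_table: dropped %d rows with missing/non-numeric values", n_dropped)
    if keep.sum() == 0:
        raise ValueError("no valid rows remain after dropping missing values")
    return DescriptorTable(
        df.loc[keep, id_column].tolist(),
        numeric.loc[keep].to_numpy(dtype=float),
        desc_cols,
        y[keep].to_numpy(dtype=float),
    )


def prune_descriptors(
    table: DescriptorTable,
    corr_threshold: float = 0.85,
    endpoint_tiebreak: bool = True,
) -> tuple[DescriptorTable, PruneLog]:
    """Remove constant/null descriptors, then the correlation filter.

    For every pair with |Pearson r| > ``corr_threshold`` (processed in
    descending |r|), the member with the smaller |corr(., y)| is dropped
    (when ``endpoint_tiebreak``), with |corr(., y)| ties broken by dropping
    the lexicographically later name.  The surviving set is therefore
    independent of input column order.
    """
    if not 0 < corr_threshold < 1:
        raise ValueError("corr_threshold must lie in (0, 1)")
    log = PruneLog()
    names = table.descriptor_names
    X = table.X
    keep = []
    for j, name in enumerate(names):
        col = X[:, j]
        if np.isnan(col).all():
            log.add(name, "null")
        elif np.nanstd(col) == 0:
            log.add(name, "constant")
        else:
            keep.append(j)

    Xk = X[:, keep]
    kept_names = [names[j] for j in keep]
    p = len(keep)
    if p >= 2:
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(Xk, rowvar=False)
        ry = np.array(
            [abs(np.corrcoef(Xk[:, j], table.y)[0, 1]) for j in range(p)]
        )
        ry = np.nan_to_num(ry)
        iu, ju = np.triu_indices(p, k=1)
        over = np.abs(C[iu, ju]) > corr_threshold
        pairs = sorted(
            zip(iu[over], ju[over], C[iu, ju][over]),
            key=lambda t: (-abs(t[2]), min(kept_names[t[0]], kept_names[t[1]]),
                           max(kept_names[t[0]], kept_names[t[1]])),
        )
        removed = set()
        for a, b, r in pairs:
            if a in removed or b in removed:
                continue
            if endpoint_tiebreak and not np.isclose(ry[a], ry[b]):
                drop = a if ry[a] < ry[b] else b
            else:
                # tie (or endpoint tie-break disabled): drop the
                # lexicographically later name
                drop = a if kept_names[a] > kept_names[b] else b
            other = b if drop == a else a
            removed.add(drop)
            log.add(kept_names[drop], "correlated", kept_names[other], float(r))
        keep = [keep[j] for j in range(p) if j not in removed]

    if len(keep) < 2:
        raise ValueError("fewer than 2 descriptors survive pruning")
    return table.subset_columns(keep), log
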