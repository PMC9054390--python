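"""Applicability-domain assessment and outlier flagging.

Two AD definitions are provided.

Leverage: h(x) = x^T (X^T X)^{-1} x over the consensus model's union
descriptor set, with warning threshold h* = 3(p+1)/n; the classic
Williams-plot abscissa.

Frequency-weighted distance (FWD): each union descriptor j is weighted by
f_j = n_j / N, the fraction of consensus sub-models that use it; compound
rows (z-score standardized on training statistics) are scaled by the
weights, and d_i is the Euclidean distance of the weighted row to the
weighted training centroid.  The threshold is mean(d) + 3 sd(d) over the
training set.  Descriptors the ensemble relies on thus dominate the
distance, unlike plain leverage which treats all descriptors equally.

Outliers are compounds whose standardized residual (residual / sd of
training residuals) exceeds 3 in magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .consensus import ConsensusModel

__all__ = [
    "LeverageAD",
    "FrequencyWeightedDistanceAD",
    "leverage_ad",
    "fwd_ad",
    "flag_outliers",
    "ADReport",
    "ad_report",
    "coverage",
]


class LeverageAD(OutlierMixin, BaseEstimator):
    """Leverage applicability domain.

    Parameters
    ----------
    p : int or None
        Descriptor count used in h* = 3(p+1)/n; defaults to the number of
        training columns.  Exposed because published thresholds sometimes
        correspond to p one below the nominal descriptor count.
    """

    def __init__(self, p: int | None = None):
        self.p = p

    def fit(self, X, y=None):
        X = check_array(X)
        n, cols = X.shape
        G = X.T @ X
        try:
            self.xtx_inv_ = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            warnings.warn("singular X^T X; using pseudo-inverse", stacklevel=2)
            self.xtx_inv_ = np.linalg.pinv(G)
        if not np.all(np.isfinite(self.xtx_inv_)):
            self.xtx_inv_ = np.linalg.pinv(G)
        p = self.p if self.p is not None else cols
        self.warning_leverage_ = 3.0 * (p + 1) / n
        self.n_train_ = n
        self.n_features_in_ = cols
        return self

    def leverage(self, X) -> np.ndarray:
        check_is_fitted(self, "xtx_inv_")
        X = check_array(X)
        return np.einsum("ij,jk,ik->i", X, self.xtx_inv_, X)

    def predict(self, X):
        """+1 inside the domain (h <= h*), -1 outside."""
        return np.where(self.leverage(X) <= self.warning_leverage_, 1, -1)


def leverage_ad(X_train, X_query, p: int | None = None) -> tuple[np.ndarray, float]:
    """Leverage values of query rows and the warning leverage 3(p+1)/n."""
    ad = LeverageAD(p=p).fit(X_train)
    return ad.leverage(X_query), ad.warning_leverage_


class FrequencyWeightedDistanceAD(OutlierMixin, BaseEstimator):
    """Frequency-weighted distance applicability domain.

    Parameters
    ----------
    standardize : bool, default=True
        z-score descriptors with training statistics before weighting;
        raw descriptor scales would otherwise dominate the distance.
    ddof : int, default=1
        Degrees of freedom for the threshold's standard deviation.
    """

    def __init__(self, standardize: bool = True, ddof: int = 1):
        self.standardize = standardize
        self.ddof = ddof

    def fit(self, X_train, consensus: ConsensusModel):
        """Fit from the training block and a fitted consensus model; uses
        the consensus union descriptors and frequencies f_j = n_j / N."""
        X_train = check_array(X_train)
        counts = consensus.usage_counts
        union = counts > 0
        if not union.any():
            raise ValueError("consensus model uses no descriptors")
        self.union_mask_ = union
        self.weights_ = counts[union] / consensus.N
        A = X_train[:, union]
        if self.standardize:
            self.mu_ = A.mean(axis=0)
            sd = A.std(axis=0)
            self.sd_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mu_ = np.zeros(union.sum())
            self.sd_ = np.ones(union.sum())
        V = ((A - self.mu_) / self.sd_) * self.weights_
        self.center_ = V.mean(axis=0)
        d = np.linalg.norm(V - self.center_, axis=1)
        self.train_distances_ = d
        self.threshold_ = float(d.mean() + 3.0 * d.std(ddof=self.ddof))
        self.n_features_in_ = X_train.shape[1]
        return self

    def distance(self, X) -> np.ndarray:
        check_is_fitted(self, "center_")
        X = check_array(X)
        V = ((X[:, self.union_mask_] - self.mu_) / self.sd_) * self.weights_
        return np.linalg.norm(V - self.center_, axis=1)

    def predict(self, X):
        """+1 inside the domain (d <= threshold), -1 outside."""
        return np.where(self.distance(X) <= self.threshold_, 1, -1)


def fwd_ad(
    cm: ConsensusModel, X_train, X_query, standardize: bool = True
) -> tuple[np.ndarray, float, np.ndarray]:
    """FWD distances of query rows, the training threshold mean+3sd, and
    the frequency weights f_j over the union descriptors."""
    ad = FrequencyWeightedDistanceAD(standardize=standardize).fit(X_train, cm)
    return ad.distance(X_query), ad.threshold_, ad.weights_


def flag_outliers(y_true, y_pred, train_mask=None, limit: float = 3.0) -> np.ndarray:
    """Indices of compounds whose standardized residual exceeds ``limit``.

    Residuals are standardized by the sd of *training* residuals
    (``train_mask`` boolean; all rows treated as training when omitted)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    resid = y_true - y_pred
    tm = np.ones(len(resid), dtype=bool) if train_mask is None else np.asarray(train_mask, dtype=bool)
    sd = resid[tm].std(ddof=1)
    if sd == 0:
        raise ValueError("zero residual standard deviation")
    return np.flatnonzero(np.abs(resid / sd) > limit)


@dataclass
class ADReport:
    """Per-compound AD assessment, one row per compound (Williams-plot data)."""

    compound_ids: list
    set_labels: np.ndarray          # "train" / "valid"
    leverage: np.ndarray
    warning_leverage: float
    fwd_distance: np.ndarray
    fwd_threshold: float
    std_residuals: np.ndarray
    inside_leverage: np.ndarray
    inside_fwd: np.ndarray
    outliers: np.ndarray            # indices with |std residual| > 3

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "set": self.set_labels,
                "leverage": self.leverage,
                "fwd_distance": self.fwd_distance,
                "std_residual": self.std_residuals,
                "inside_leverage": self.inside_leverage,
                "inside_fwd": self.inside_fwd,
                "outlier": np.isin(np.arange(len(self.compound_ids)), self.outliers),
            }
        )


def ad_report(
    cm: ConsensusModel,
    X_train,
    y_train,
    X_valid,
    y_valid,
    compound_ids_train=None,
    compound_ids_valid=None,
    leverage_p: int | None = None,
    standardize_fwd: bool = True,
) -> ADReport:
    """Full AD assessment of a consensus model over train + validation."""
    X_train = np.asarray(X_train, dtype=float)
    X_valid = np.asarray(X_valid, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_valid = np.asarray(y_valid, dtype=float)
    n_tr, n_va = len(y_train), len(y_valid)

    union = cm.union_mask
    p = leverage_p if leverage_p is not None else int(union.sum())
    lev = LeverageAD(p=p).fit(X_train[:, union])
    h_tr = lev.leverage(X_train[:, union])
    h_va = lev.leverage(X_valid[:, union])

    fwd = FrequencyWeightedDistanceAD(standardize=standardize_fwd).fit(X_train, cm)
    d_tr = fwd.train_distances_
    d_va = fwd.distance(X_valid)

    yhat_tr = cm.predict(X_train)
    yhat_va = cm.predict(X_valid)
    resid = np.concatenate([y_train - yhat_tr, y_valid - yhat_va])
    sd = (y_train - yhat_tr).std(ddof=1)
    if sd == 0:
        raise ValueError("zero training residual standard deviation")
    std_resid = resid / sd

    ids_tr = list(compound_ids_train) if compound_ids_train is not None else [f"train{i}" for i in range(n_tr)]
    ids_va = list(compound_ids_valid) if compound_ids_valid is not None else [f"valid{i}" for i in range(n_va)]
    h = np.concatenate([h_tr, h_va])
    d = np.concatenate([d_tr, d_va])
    return ADReport(
        compound_ids=ids_tr + ids_va,
        set_labels=np.array(["train"] * n_tr + ["valid"] * n_va),
        leverage=h,
        warning_leverage=lev.warning_leverage_,
        fwd_distance=d,
        fwd_threshold=fwd.threshold_,
        std_residuals=std_resid,
        inside_leverage=h <= lev.warning_leverage_,
        inside_fwd=d <= fwd.threshold_,
        outliers=np.flatnonzero(np.abs(std_resid) > 3.0),
    )


def coverage(report: ADReport, method: str = "fwd") -> dict:
    """Fraction of compounds inside the AD per set."""
    inside = report.inside_fwd if method == "fwd" else report.inside_leverage
    out = {}
    for s in ("train", "valid"):
        m = report.set_labels == s
        out[s] = float(inside[m].mean()) if m.any() else np.nan
    return out
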