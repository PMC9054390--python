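"""Internal and external validation metrics for QSAR regression models.

Conventions (with y observed, yhat predicted):

* R^2 (fit)         : 1 - sum (y - yhat)^2 / sum (y - mean(y))^2
* R^2_cv10          : same form over out-of-fold predictions from 10-fold CV
* R^2_ext           : external set, centred on the validation mean
* Q^2_ext           : external set, centred on the *training* mean
* R^2_adj           : 1 - (1 - R^2)(n - 1)/(n - p - 1)
* Golbraikh-Tropsha : through-origin slopes k, k' and determination
                      coefficients; acceptance when 0.85 < k, k' < 1.15 and
                      (R0^2 - R0'^2)/R0^2 < 0.1
* y-randomization   : refit on shuffled endpoints; a sound model collapses
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .rbf import RBFNetRegressor

__all__ = [
    "fit_metrics",
    "make_folds",
    "cv10",
    "adjusted_r2",
    "golbraikh_tropsha",
    "GTResult",
    "y_randomization",
    "ValidationReport",
    "validation_report",
]


def fit_metrics(y_true, y_pred, centering: str = "self", train_mean: float | None = None) -> float:
    """Coefficient-of-determination-style metric with selectable centering.

    ``centering="self"`` uses mean(y_true) (R^2 / R^2_ext semantics);
    ``centering="train_mean"`` uses the supplied training mean (Q^2_ext)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    if centering == "self":
        c = y_true.mean()
    elif centering == "train_mean":
        if train_mean is None:
            raise ValueError("train_mean required for centering='train_mean'")
        c = float(train_mean)
    else:
        raise ValueError(f"unknown centering {centering!r}")
    denom = float(((y_true - c) ** 2).sum())
    if denom == 0:
        raise ValueError("zero denominator: constant y against its centering constant")
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / denom


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment: shuffle indices with the seed, deal round-robin."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


def cv10(
    X,
    y,
    mse_goal: float,
    spread: float,
    max_neurons: int = 500,
    seed: int = 0,
    n_folds: int = 10,
    folds=None,
    basis: str = "halfwidth",
) -> tuple[float, np.ndarray]:
    """10-fold cross-validated R^2: every compound predicted exactly once by
    a model fitted without it.  Returns (R^2_cv, out-of-fold predictions)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds is None:
        if n < n_folds:
            raise ValueError(f"need at least {n_folds} samples for {n_folds}-fold CV")
        folds = make_folds(n, n_folds, seed)
    folds = np.asarray(folds)
    oof = np.empty(n)
    for f in np.unique(folds):
        test = folds == f
        model = RBFNetRegressor(
            mse_goal=mse_goal, spread=spread, max_neurons=max_neurons, basis=basis
        ).fit(X[~test], y[~test])
        oof[test] = model.predict(X[test])
    return fit_metrics(y, oof, centering="self"), oof


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination for p predictors, n samples."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n} <= p+1={p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class GTResult:
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    gt_ratio: float
    passed: bool


def golbraikh_tropsha(y_true, y_pred) -> GTResult:
    """External-predictivity criteria via regression through the origin."""
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if len(y) != len(yh) or len(y) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if (yh**2).sum() == 0:
        raise ValueError("all predictions are zero")
    k = float((y * yh).sum() / (yh**2).sum())
    k_prime = float((y * yh).sum() / (y**2).sum())
    r0 = 1.0 - float(((y - k * yh) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    r0p = 1.0 - float(((yh - k_prime * y) ** 2).sum() / ((yh - yh.mean()) ** 2).sum())
    ratio = (r0 - r0p) / r0 if r0 != 0 else np.inf
    passed = (0.85 < k < 1.15) and (0.85 < k_prime < 1.15) and abs(ratio) < 0.1
    return GTResult(k, k_prime, r0, r0p, float(ratio), bool(passed))


def y_randomization(
    X,
    y,
    mse_goal: float,
    spread: float,
    n_rounds: int = 10,
    seed: int = 0,
    max_neurons: int = 500,
    n_folds: int = 10,
    basis: str = "halfwidth",
) -> list[tuple[float, float]]:
    """Shuffle the endpoint and refit with unchanged hyperparameters and
    descriptors; returns (R^2, R^2_cv10) per round."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_rounds):
        y_perm = rng.permutation(y)
        model = RBFNetRegressor(
            mse_goal=mse_goal, spread=spread, max_neurons=max_neurons, basis=basis
        ).fit(X, y_perm)
        r2 = fit_metrics(y_perm, model.predict(X))
        r2cv, _ = cv10(
            X, y_perm, mse_goal, spread, max_neurons,
            seed=int(rng.integers(2**31)), n_folds=n_folds, basis=basis,
        )
        out.append((r2, r2cv))
    return out


@dataclass
class ValidationReport:
    r2: float
    r2_adj: float
    r2_cv10: float
    r2_ext: float
    q2_ext: float
    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    gt_ratio: float
    gt_passed: bool
    topliss_ratio: float
    n_train: int
    n_valid: int
    n_descriptors: int
    yrand: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def validation_report(
    model,
    X_train,
    y_train,
    X_valid,
    y_valid,
    mse_goal: float,
    spread: float,
    n_descriptors: int,
    max_neurons: int = 500,
    cv_seed: int = 0,
    yrand_rounds: int = 0,
    yrand_seed: int = 0,
    basis: str = "halfwidth",
) -> ValidationReport:
    """Full internal + external validation of a fitted model."""
    y_train = np.asarray(y_train, dtype=float)
    y_valid = np.asarray(y_valid, dtype=float)
    yhat_tr = model.predict(X_train)
    yhat_va = model.predict(X_valid)
    r2 = fit_metrics(y_train, yhat_tr)
    r2cv, _ = cv10(X_train, y_train, mse_goal, spread, max_neurons, seed=cv_seed, basis=basis)
    gt = golbraikh_tropsha(y_valid, yhat_va)
    yrand = (
        y_randomization(
            X_train, y_train, mse_goal, spread, yrand_rounds, yrand_seed,
            max_neurons, basis=basis,
        )
        if yrand_rounds
        else []
    )
    return ValidationReport(
        r2=r2,
        r2_adj=adjusted_r2(r2, len(y_train), n_descriptors),
        r2_cv10=r2cv,
        r2_ext=fit_metrics(y_valid, yhat_va, centering="self"),
        q2_ext=fit_metrics(y_valid, yhat_va, centering="train_mean", train_mean=y_train.mean()),
        k=gt.k,
        k_prime=gt.k_prime,
        r0_sq=gt.r0_sq,
        r0_prime_sq=gt.r0_prime_sq,
        gt_ratio=gt.gt_ratio,
        gt_passed=gt.passed,
        topliss_ratio=len(y_train) / n_descriptors,
        n_train=len(y_train),
        n_valid=len(y_valid),
        n_descriptors=n_descriptors,
        yrand=yrand,
    )
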