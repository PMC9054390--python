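"""Radial basis function network regression.

The model is a single-hidden-layer network with Gaussian units centred on
training points,

    yhat(x) = sum_i  w_i * phi(||x - c_i||; delta)  (+ bias),

trained by greedy incremental centre addition: at every step the training
input whose inclusion most reduces the residual sum of squares is promoted
to a centre, and the output weights (plus optional bias) are re-solved by
linear least squares.  Training stops once the training MSE reaches the
goal ``mse_goal`` or the neuron budget ``max_neurons`` is exhausted.

Two basis conventions are supported.  The default, ``"halfwidth"``, defines
phi(d) = exp(-(0.8326 d / delta)^2) so that phi(delta) = 0.5 — the spread
semantics of the classic neural-network toolboxes this family of QSAR
models was built with.  ``"plain"`` gives phi(d) = exp(-(d/delta)^2).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "RBFNetRegressor",
    "fit_rbf",
    "predict_rbf",
    "gaussian_basis",
    "TrainingStallWarning",
]


class TrainingStallWarning(UserWarning):
    """Greedy centre addition stalled before reaching the MSE goal."""

# exp(-(HALFWIDTH_FACTOR)^2) = 0.5, i.e. sqrt(ln 2)
_HALFWIDTH_FACTOR = 0.8326


def _solve_ls(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares via normal equations, falling back to lstsq when the
    Gram matrix is ill-conditioned."""
    G = design.T @ design
    try:
        coef = np.linalg.solve(G, design.T @ y)
        if np.all(np.isfinite(coef)):
            return coef
    except np.linalg.LinAlgError:
        pass
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def gaussian_basis(dist: np.ndarray, spread: float, basis: str = "halfwidth") -> np.ndarray:
    """Evaluate the Gaussian unit phi(d; spread) element-wise on distances."""
    if spread <= 0:
        raise ValueError(f"spread must be positive, got {spread}")
    if basis == "halfwidth":
        return np.exp(-((_HALFWIDTH_FACTOR * dist / spread) ** 2))
    if basis == "plain":
        return np.exp(-((dist / spread) ** 2))
    raise ValueError(f"unknown basis convention {basis!r}")


class RBFNetRegressor(RegressorMixin, BaseEstimator):
    """Gaussian RBF network trained by greedy centre selection.

    Parameters
    ----------
    mse_goal : float, default=0.01
        Training MSE target (units of y squared).  Centre addition stops as
        soon as the training MSE drops to this value.  Smaller goals give
        stronger fitting ability at the cost of over-fitting risk.
    spread : float, default=1.0
        Width delta of the Gaussian units; one shared value for all units.
    max_neurons : int, default=500
        Hard cap on the number of hidden units.
    basis : {"halfwidth", "plain"}, default="halfwidth"
        Basis convention, see module docstring.
    fit_bias : bool, default=True
        Include a constant output-layer bias.  The textbook network output
        has no bias term; toolbox implementations include one, and the
        (mse_goal, spread) ranges used in this package assume it.

    Attributes
    ----------
    centers_ : ndarray of shape (k, p)
        Selected centres (copies of training rows).
    weights_ : ndarray of shape (k,)
        Output-layer weights.
    bias_ : float
        Output bias (0.0 when ``fit_bias=False``).
    n_neurons_ : int
        Number of hidden units k.
    train_mse_ : float
        Final training MSE.
    mse_path_ : ndarray
        Training MSE after each centre addition.
    """

    def __init__(
        self,
        mse_goal: float = 0.01,
        spread: float = 1.0,
        max_neurons: int = 500,
        basis: str = "halfwidth",
        fit_bias: bool = True,
    ):
        self.mse_goal = mse_goal
        self.spread = spread
        self.max_neurons = max_neurons
        self.basis = basis
        self.fit_bias = fit_bias

    def fit(self, X, y):
        # internal callers pass pre-validated float arrays; skip the
        # (comparatively expensive) sklearn validation for those
        if not (
            isinstance(X, np.ndarray)
            and X.dtype == np.float64
            and X.ndim == 2
            and isinstance(y, np.ndarray)
            and y.dtype == np.float64
            and y.ndim == 1
            and len(y) == X.shape[0]
        ):
            X, y = check_X_y(X, y, y_numeric=True)
        if self.mse_goal <= 0:
            raise ValueError("mse_goal must be positive")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        n = X.shape[0]
        y = y.astype(float, copy=False)

        # kernel matrix: column j is candidate basis function centred on row j
        K = gaussian_basis(cdist(X, X), self.spread, self.basis)

        # Greedy orthogonal least squares.  K_orth holds the candidate
        # columns orthogonalised against the current design; the score
        # vector a = r.K_orth and column norms b are updated incrementally.
        cols = []
        r = y.copy()
        K_orth = K.copy()
        if self.fit_bias:
            q = np.full(n, 1.0 / np.sqrt(n))
            r = r - q * (q @ r)
            K_orth -= q[:, None] * (q @ K_orth)[None, :]

        a = r @ K_orth
        b = np.einsum("ij,ij->j", K_orth, K_orth)
        rss = float(r @ r)
        available = np.ones(n, dtype=bool)
        y_var = max(float(y.var()), 1e-30)
        mse_path = []
        budget = min(self.max_neurons, n)
        while len(cols) < budget:
            if rss / n <= self.mse_goal:
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(available & (b > 1e-12), a * a / np.maximum(b, 1e-300), -np.inf)
            j = int(np.argmax(scores))
            if not np.isfinite(scores[j]) or scores[j] <= 1e-14:
                # no candidate reduces the residual (degenerate design,
                # e.g. identical inputs with conflicting targets); stay
                # quiet when the fit is already at numerical precision
                if rss / n > 1e-6 * y_var:
                    warnings.warn(
                        "RBF training stalled before reaching mse_goal; "
                        "returning best least-squares fit",
                        TrainingStallWarning,
                        stacklevel=2,
                    )
                break
            cols.append(j)
            available[j] = False
            q = K_orth[:, j] / np.sqrt(b[j])
            qr = float(q @ r)
            c = q @ K_orth
            r -= q * qr
            K_orth -= q[:, None] * c[None, :]
            a -= qr * c
            b = np.maximum(b - c * c, 0.0)
            rss = max(rss - qr * qr, 0.0)
            mse_path.append(rss / n)

        cols_arr = np.array(cols, dtype=int)
        # final re-solve on the raw (un-orthogonalised) design for clean
        # weight/bias values
        if self.fit_bias:
            design = np.column_stack([np.ones(n), K[:, cols_arr]])
        else:
            design = K[:, cols_arr] if len(cols) else np.zeros((n, 0))
        if design.shape[1] > 0:
            coef = _solve_ls(design, y)
        else:
            coef = np.zeros(0)
        if self.fit_bias:
            self.bias_ = float(coef[0])
            self.weights_ = coef[1:]
        else:
            self.bias_ = 0.0
            self.weights_ = coef
        self.centers_ = X[cols_arr].copy()
        self.center_indices_ = cols_arr
        self.n_neurons_ = len(cols)
        resid = y - design @ coef if design.shape[1] else y
        self.train_mse_ = float(resid @ resid) / n
        self.mse_path_ = np.asarray(mse_path)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "centers_")
        if not (isinstance(X, np.ndarray) and X.dtype == np.float64 and X.ndim == 2):
            X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        if self.n_neurons_ == 0:
            return np.full(X.shape[0], self.bias_)
        Phi = gaussian_basis(cdist(X, self.centers_), self.spread, self.basis)
        return Phi @ self.weights_ + self.bias_

    # -- serialization ----------------------------------------------------

    def to_dict(self, descriptor_names=None) -> dict:
        check_is_fitted(self, "centers_")
        return {
            "mse_goal": self.mse_goal,
            "spread": self.spread,
            "max_neurons": self.max_neurons,
            "basis": self.basis,
            "fit_bias": self.fit_bias,
            "centers": self.centers_.tolist(),
            "weights": self.weights_.tolist(),
            "bias": self.bias_,
            "train_mse": self.train_mse_,
            "descriptor_names": list(descriptor_names) if descriptor_names is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFNetRegressor":
        model = cls(
            mse_goal=d["mse_goal"],
            spread=d["spread"],
            max_neurons=d["max_neurons"],
            basis=d["basis"],
            fit_bias=d["fit_bias"],
        )
        model.centers_ = np.asarray(d["centers"], dtype=float)
        model.weights_ = np.asarray(d["weights"], dtype=float)
        model.bias_ = float(d["bias"])
        model.train_mse_ = float(d["train_mse"])
        model.n_neurons_ = model.centers_.shape[0]
        model.n_features_in_ = model.centers_.shape[1] if model.n_neurons_ else 0
        model.center_indices_ = np.arange(model.n_neurons_)
        model.mse_path_ = np.asarray([])
        return model

    def save(self, path, descriptor_names=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(descriptor_names), fh)

    @classmethod
    def load(cls, path) -> "RBFNetRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_rbf(X_train, y_train, mse_goal, spread, max_neurons=500, **kwargs) -> RBFNetRegressor:
    """Fit an RBF network; functional wrapper over :class:`RBFNetRegressor`."""
    return RBFNetRegressor(
        mse_goal=mse_goal, spread=spread, max_neurons=max_neurons, **kwargs
    ).fit(X_train, y_train)


def predict_rbf(model: RBFNetRegressor, X_query) -> np.ndarray:
    """Evaluate a fitted RBF network on query rows."""
    return model.predict(X_query)
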