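"""Least-squares support vector regression with an RBF kernel.

Training reduces to one dense linear (KKT) system

    [ 0   1^T          ] [ b     ]   [ 0 ]
    [ 1   Omega + I/C  ] [ alpha ] = [ y ],   Omega_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)),

whose solution satisfies sum(alpha) = 0 (the bias-constraint identity).
Prediction is f(x) = sum_i alpha_i k(x, x_i) + b.  A multi-output wrapper
fits one model per face-latent dimension over shared, standardized inputs
(the kernel matrix is factorized once), and an attribute augmenter appends
z-scored age/BMI columns to the latent inputs, reusing training statistics
at reconstruction time.  Hyperparameters default to C=1000, sigma^2=100 and
can be tuned by seeded k-fold cross-validation over log-spaced grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist

__all__ = [
    "LSSVRModel",
    "MultiOutputLSSVR",
    "AttributeScaler",
    "train_lssvr",
    "predict_lssvr",
    "train_multi",
    "tune_hyperparams",
    "augment_with_attributes",
]


def _rbf_gram(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma2))


def _kkt_solve(Omega: np.ndarray, Y: np.ndarray, C_reg: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve the LSSVR KKT system for (possibly several) target columns."""
    n = len(Omega)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = Omega + np.eye(n) / C_reg
    rhs = np.zeros((n + 1, Y.shape[1]))
    rhs[1:] = Y
    try:
        lu = lu_factor(A)
        sol = lu_solve(lu, rhs)
    except (np.linalg.LinAlgError, ValueError):
        A[1:, 1:] += 1e-10 * np.eye(n)
        sol = lu_solve(lu_factor(A), rhs)
    b = sol[0]
    alpha = sol[1:]
    return alpha, b


@dataclass
class LSSVRModel:
    """A single-output LSSVR: support inputs, support values alpha, bias b."""

    support_X: np.ndarray
    alpha: np.ndarray
    b: float
    sigma2: float
    C_reg: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.alpha)) and np.isfinite(self.b)):
            raise ValueError("non-finite LSSVR solution")

    def predict(self, x: np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.support_X.shape[1]:
            raise ValueError("input dimension mismatch with support inputs")
        k = _rbf_gram(X, self.support_X, self.sigma2)
        out = k @ self.alpha + self.b
        return float(out[0]) if single else out


def train_lssvr(X: np.ndarray, y: np.ndarray, C_reg: float = 1000.0, sigma2: float = 100.0) -> LSSVRModel:
    """Train a single-output LSSVR by solving the dual KKT system."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if len(X) < 2:
        raise ValueError("need at least 2 training points")
    if C_reg <= 0 or sigma2 <= 0:
        raise ValueError("C_reg and sigma2 must be positive")
    Omega = _rbf_gram(X, X, sigma2)
    alpha, b = _kkt_solve(Omega, y[:, None], C_reg)
    return LSSVRModel(X.copy(), alpha[:, 0], float(b[0]), sigma2, C_reg)


def predict_lssvr(model: LSSVRModel, x: np.ndarray):
    """f(x) = sum_i alpha_i exp(-||x - x_i||^2 / (2 sigma^2)) + b."""
    return model.predict(x)


@dataclass
class MultiOutputLSSVR:
    """Independent LSSVR per output dimension over shared standardized inputs."""

    models: list[LSSVRModel]
    input_mean: np.ndarray
    input_scale: np.ndarray

    @property
    def n_outputs(self) -> int:
        return len(self.models)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        Xs = (X - self.input_mean) / self.input_scale
        out = np.column_stack([m.predict(Xs) for m in self.models])
        return out[0] if single else out


def train_multi(
    X: np.ndarray, Y: np.ndarray, C_reg: float = 1000.0, sigma2: float = 100.0
) -> MultiOutputLSSVR:
    """Train one LSSVR per column of Y; inputs standardized once."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(X) != len(Y):
        raise ValueError("X and Y row counts differ")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 1e-12, scale, 1.0)
    Xs = (X - mean) / scale
    Omega = _rbf_gram(Xs, Xs, sigma2)
    alpha, b = _kkt_solve(Omega, Y, C_reg)
    models = [
        LSSVRModel(Xs.copy(), alpha[:, j], float(b[j]), sigma2, C_reg) for j in range(Y.shape[1])
    ]
    return MultiOutputLSSVR(models, mean, scale)


def tune_hyperparams(
    X: np.ndarray,
    Y: np.ndarray,
    C_grid=None,
    sigma2_grid=None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Seeded k-fold grid search for (C, sigma^2), MSE criterion.

    Grids default to log-spaced ranges centered on the customary starting
    point C=1000, sigma^2=100.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(X)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if C_grid is None:
        C_grid = np.logspace(2, 5, 4)
    if sigma2_grid is None:
        sigma2_grid = np.logspace(0, 3, 4)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for k in range(folds):
        fold_of[perm[k::folds]] = k
    rows = []
    best = (np.inf, None, None)
    for C_reg in C_grid:
        for sigma2 in sigma2_grid:
            sse, cnt = 0.0, 0
            for k in range(folds):
                tr = fold_of != k
                te = ~tr
                model = train_multi(X[tr], Y[tr], C_reg, sigma2)
                pred = model.predict(X[te])
                sse += float(((pred - Y[te]) ** 2).sum())
                cnt += int(te.sum()) * Y.shape[1]
            mse = sse / cnt
            rows.append({"C_reg": C_reg, "sigma2": sigma2, "cv_mse": mse})
            if mse < best[0]:
                best = (mse, float(C_reg), float(sigma2))
    table = pd.DataFrame(rows)
    return best[1], best[2], table


@dataclass
class AttributeScaler:
    """z-scoring of attribute columns with training statistics stored for
    reconstruction-time reuse."""

    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, attrs: pd.DataFrame, columns=("age", "bmi")) -> "AttributeScaler":
        cols = list(columns)
        missing = [c for c in cols if c not in attrs.columns]
        if missing:
            raise KeyError(f"missing attribute columns: {missing}")
        vals = attrs[cols].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("attributes contain missing/non-finite values")
        mean = vals.mean(axis=0)
        scale = vals.std(axis=0)
        zero = scale <= 1e-12
        if zero.any():
            raise ValueError(
                f"attribute column(s) {list(np.asarray(cols)[zero])} have zero variance"
            )
        return cls(cols, mean, scale)

    def transform(self, attrs) -> np.ndarray:
        if isinstance(attrs, pd.DataFrame):
            vals = attrs[self.columns].to_numpy(float)
        else:
            vals = np.atleast_2d(np.asarray(attrs, float))
        return (vals - self.mean) / self.scale


def augment_with_attributes(
    latents: np.ndarray,
    attrs: pd.DataFrame,
    scaler: AttributeScaler | None = None,
    columns=("age", "bmi"),
) -> tuple[np.ndarray, AttributeScaler | None]:
    """Concatenate z-scored attribute columns after the latent dims.

    With an empty column list this is the identity.  Pass a fitted scaler to
    reuse training statistics on held-out rows.
    """
    latents = np.atleast_2d(np.asarray(latents, float))
    cols = list(columns)
    if not cols:
        return latents, scaler
    if len(attrs) != len(latents):
        raise ValueError("attribute rows do not align with latent rows")
    if scaler is None:
        scaler = AttributeScaler.fit(attrs, cols)
    z = scaler.transform(attrs)
    return np.hstack([latents, z]), scaler
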