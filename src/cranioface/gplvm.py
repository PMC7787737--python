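"""Gaussian process latent variable model for regional shape spaces.

One GP-LVM is fitted per modality x region: the M regional shape vectors
(rows of Y, dimension D = 3 x region vertex count) are modelled as D
independent GP outputs over shared latent coordinates X (M x q) under an
ARD squared-exponential kernel

    k(x, x') = sigma_f^2 exp(-1/2 sum_d (x_d - x'_d)^2 / M_d),

with M_d a per-dimension (squared) lengthscale.  Latent coordinates and the
log-hyperparameters are optimized jointly by L-BFGS on the log marginal
likelihood

    L = -(D/2) log|K + sn2 I| - 1/2 tr((K + sn2 I)^{-1} Y Y^T)
        - (M D / 2) log 2 pi.

Decoding maps a latent point to the posterior mean shape (plus the stored
data mean) with its predictive variance; encoding projects an unseen shape
into latent space by minimizing its negative predictive log-density, started
from the latent of the nearest training shape.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "KernelParams",
    "LatentModel",
    "se_kernel",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit_gplvm",
    "decode",
    "encode",
    "choose_latent_dim",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


@dataclass
class KernelParams:
    """ARD squared-exponential kernel hyperparameters (all strictly positive).

    ``lengthscales`` holds the per-latent-dimension scales M_d dividing the
    squared distance; ``signal_var`` is sigma_f^2 and ``noise_var`` sigma_n^2.
    """

    lengthscales: np.ndarray
    signal_var: float
    noise_var: float

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=np.float64))
        if np.any(self.lengthscales <= 0) or self.signal_var <= 0 or self.noise_var <= 0:
            raise ValueError("kernel parameters must be strictly positive")

    def log_vector(self) -> np.ndarray:
        return np.concatenate([np.log(self.lengthscales), [np.log(self.signal_var), np.log(self.noise_var)]])

    @classmethod
    def from_log_vector(cls, v: np.ndarray, q: int) -> "KernelParams":
        v = np.asarray(v, dtype=np.float64)
        return cls(np.exp(v[:q]), float(np.exp(v[q])), float(np.exp(v[q + 1])))


def se_kernel(x: np.ndarray, x2: np.ndarray, params: KernelParams) -> float:
    """Squared-exponential covariance between two latent points."""
    x = np.atleast_1d(np.asarray(x, float))
    x2 = np.atleast_1d(np.asarray(x2, float))
    if x.shape != x2.shape or x.size != params.lengthscales.size:
        raise ValueError("latent dimension mismatch with lengthscales")
    d2 = ((x - x2) ** 2 / params.lengthscales).sum()
    return float(params.signal_var * np.exp(-0.5 * d2))


def kernel_matrix(X: np.ndarray, X2: np.ndarray, params: KernelParams) -> np.ndarray:
    """Cross-covariance matrix between two latent point sets."""
    X = np.atleast_2d(X)
    X2 = np.atleast_2d(X2)
    s = np.sqrt(params.lengthscales)
    A = X / s
    B = X2 / s
    d2 = (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2.0 * A @ B.T
    return params.signal_var * np.exp(-0.5 * np.maximum(d2, 0.0))


def _chol_with_jitter(Kn: np.ndarray):
    base = np.mean(np.diag(Kn))
    for j in _JITTERS:
        try:
            return cho_factor(Kn + j * base * np.eye(len(Kn)), lower=True), j * base
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("Cholesky failed after jitter escalation")


def log_marginal_likelihood(
    X: np.ndarray,
    Y_centered: np.ndarray,
    params: KernelParams,
    with_grad: bool = False,
):
    """GP-LVM log marginal likelihood (and optionally its gradients).

    Returns L, or (L, grad_X, grad_logparams) where grad_logparams is the
    gradient with respect to (log M_1..log M_q, log sigma_f^2, log sigma_n^2).
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y_centered, float))
    M, q = X.shape
    D = Y.shape[1]
    K = kernel_matrix(X, X, params)
    Kn = K + params.noise_var * np.eye(M)
    (c, lower), _ = _chol_with_jitter(Kn)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    Ki = cho_solve((c, lower), np.eye(M))
    YYT = Y @ Y.T
    trace_term = float((Ki * YYT).sum())
    L = -0.5 * D * logdet - 0.5 * trace_term - 0.5 * M * D * np.log(2.0 * np.pi)
    if not with_grad:
        return float(L)
    # dL/dKn = 1/2 (Ki YYT Ki - D Ki)
    KiYKi = Ki @ YYT @ Ki
    W = 0.5 * (0.5 * (KiYKi + KiYKi.T) - D * Ki)
    B = W * K
    grad_X = np.empty_like(X)
    for d in range(q):
        xd = X[:, d]
        grad_X[:, d] = (-2.0 / params.lengthscales[d]) * (xd * B.sum(axis=1) - B @ xd)
    grad_logp = np.empty(q + 2)
    for d in range(q):
        G = (X[:, d][:, None] - X[:, d][None, :]) ** 2
        grad_logp[d] = 0.5 / params.lengthscales[d] * float((B * G).sum())
    grad_logp[q] = float(B.sum())  # d/d log sf2: dKn = K -> tr(W K)
    grad_logp[q + 1] = params.noise_var * float(np.trace(W))
    return float(L), grad_X, grad_logp


def _pca_scores(Y: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    U, sig, _ = np.linalg.svd(Y, full_matrices=False)
    scores = U[:, :q] * sig[:q]
    return scores, sig


def choose_latent_dim(Y_centered: np.ndarray, cap: int = 8, var_frac: float = 0.99) -> int:
    """Smallest dimension explaining var_frac of PCA variance, capped."""
    _, sig, _ = np.linalg.svd(Y_centered, full_matrices=False)
    v = sig**2
    if v.sum() <= 0:
        return 1
    frac = np.cumsum(v) / v.sum()
    q = int(np.searchsorted(frac, var_frac) + 1)
    return max(1, min(q, cap, Y_centered.shape[0] - 2))


@dataclass
class LatentModel:
    """A fitted GP-LVM for one modality x region."""

    X: np.ndarray
    Y_centered: np.ndarray
    data_mean: np.ndarray
    params: KernelParams
    modality: str = ""
    region: str = ""
    final_lml: float = 0.0
    init_lml: float = 0.0

    def __post_init__(self) -> None:
        self._factorize()

    def _factorize(self) -> None:
        M = len(self.X)
        Kn = kernel_matrix(self.X, self.X, self.params) + self.params.noise_var * np.eye(M)
        (c, lower), jit = _chol_with_jitter(Kn)
        self._chol = (c, lower)
        self._jitter = jit
        self._alpha = cho_solve((c, lower), self.Y_centered)  # (M, D)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def D(self) -> int:
        return self.Y_centered.shape[1]

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "latent_model.npz",
            X=self.X,
            Y_centered=self.Y_centered,
            data_mean=self.data_mean,
            lengthscales=self.params.lengthscales,
        )
        meta = {
            "signal_var": self.params.signal_var,
            "noise_var": self.params.noise_var,
            "modality": self.modality,
            "region": self.region,
            "q": self.q,
            "final_lml": self.final_lml,
            "init_lml": self.init_lml,
        }
        (d / "latent_model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "LatentModel":
        d = Path(directory)
        arrays = np.load(d / "latent_model.npz")
        meta = json.loads((d / "latent_model.json").read_text())
        params = KernelParams(arrays["lengthscales"], meta["signal_var"], meta["noise_var"])
        return cls(
            arrays["X"],
            arrays["Y_centered"],
            arrays["data_mean"],
            params,
            meta["modality"],
            meta["region"],
            meta["final_lml"],
            meta["init_lml"],
        )


def fit_gplvm(
    Y: np.ndarray,
    q: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
    gtol: float = 1e-6,
    modality: str = "",
    region: str = "",
) -> LatentModel:
    """Fit a GP-LVM to shape vectors Y (M x D).

    Latent coordinates are initialized from PCA scores (scaled to unit RMS)
    and optimized jointly with log-hyperparameters by L-BFGS-B on the log
    marginal likelihood.  Deterministic for a given seed.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    M, D = Y.shape
    mean = Y.mean(axis=0)
    Yc = Y - mean
    if q is None:
        q = choose_latent_dim(Yc)
    if M < q + 2:
        raise ValueError(f"need at least q+2={q + 2} samples, got {M}")
    scores, _ = _pca_scores(Yc, q)
    rms = np.sqrt((scores**2).mean())
    X0 = scores / rms if rms > 0 else np.random.default_rng(seed).normal(0, 1e-3, (M, q))
    total_var = float((Yc**2).sum() / (M * D))
    params0 = KernelParams(np.ones(q), max(total_var, 1e-8), max(0.01 * total_var, 1e-10))
    theta0 = np.concatenate([X0.ravel(), params0.log_vector()])

    def objective(theta):
        Xc = theta[: M * q].reshape(M, q)
        p = KernelParams.from_log_vector(theta[M * q :], q)
        L, gX, gp = log_marginal_likelihood(Xc, Yc, p, with_grad=True)
        return -L, -np.concatenate([gX.ravel(), gp])

    init_lml = -objective(theta0)[0]
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"GP-LVM optimizer diverged: {res.message}")
    Xf = res.x[: M * q].reshape(M, q)
    pf = KernelParams.from_log_vector(res.x[M * q :], q)
    final_lml = float(-res.fun)
    return LatentModel(Xf, Yc, mean, pf, modality, region, final_lml, float(init_lml))


def decode(model: LatentModel, x_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean shape(s) and predictive variance(s) at latent point(s).

    Returns (mean, var): mean includes the stored data mean; var is the
    per-point GP posterior variance k** - k^T (K + sn2 I)^{-1} k, clipped to
    [0, sigma_f^2 + jitter].
    """
    x = np.atleast_2d(np.asarray(x_star, float))
    if x.shape[1] != model.q:
        raise ValueError(f"latent dim mismatch: got {x.shape[1]}, model has {model.q}")
    k = kernel_matrix(x, model.X, model.params)  # (k, M)
    mean = k @ model._alpha + model.data_mean
    v = cho_solve(model._chol, k.T)  # (M, k)
    var = model.params.signal_var - (k * v.T).sum(axis=1)
    var = np.clip(var, 0.0, model.params.signal_var + model._jitter + 1e-12)
    if np.asarray(x_star).ndim == 1:
        return mean[0], float(var[0])
    return mean, var


def _encode_objective(model: LatentModel, y_c: np.ndarray, x: np.ndarray):
    """Negative predictive log-density of y (centered) at latent x, + grad."""
    p = model.params
    k = kernel_matrix(x[None, :], model.X, p)[0]  # (M,)
    a = cho_solve(model._chol, k)  # (M,)
    mu = model._alpha.T @ k  # (D,)
    s2 = float(p.signal_var - k @ a) + p.noise_var
    s2 = max(s2, 1e-12)
    r = mu - y_c
    D = model.D
    nll = 0.5 * D * np.log(2.0 * np.pi * s2) + 0.5 * float(r @ r) / s2
    # dk/dx: (M, q)
    dk = k[:, None] * (-(x[None, :] - model.X) / p.lengthscales[None, :])
    dmu = model._alpha.T @ dk  # (D, q) -- via chain on k
    ds2 = -2.0 * a @ dk  # (q,)
    grad = (r @ dmu) / s2 + (0.5 * D / s2 - 0.5 * float(r @ r) / s2**2) * ds2
    return nll, grad


def encode(
    model: LatentModel,
    y_new: np.ndarray,
    init: np.ndarray | str = "nn",
    max_iter: int = 200,
) -> np.ndarray:
    """Project an unseen shape vector into the latent space.

    Minimizes the negative predictive log-density of ``y_new`` under the
    model (posterior mean and variance jointly) by L-BFGS, started either
    from a user-supplied latent point or from the latent coordinate of the
    nearest training shape ("nn").
    """
    y = np.asarray(y_new, float).ravel()
    if y.size != model.D:
        raise ValueError(f"shape vector length {y.size} != model D {model.D}")
    y_c = y - model.data_mean
    if isinstance(init, str):
        if init != "nn":
            raise ValueError("init must be a latent vector or 'nn'")
        i = int(np.argmin(((model.Y_centered - y_c) ** 2).sum(axis=1)))
        x0 = model.X[i].copy()
    else:
        x0 = np.asarray(init, float).ravel()
        if x0.size != model.q:
            raise ValueError("init latent dimension mismatch")

    def obj(x):
        return _encode_objective(model, y_c, x)

    res = minimize(obj, x0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter})
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        warnings.warn(f"encode optimizer did not fully converge: {res.message}")
    return np.asarray(res.x, float)
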