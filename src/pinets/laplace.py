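"""Laplace approximation: Gaussian parameter posterior from the Fisher
information at the MAP estimate.

The "gradient" construction uses the model expectation of the score outer
product: for the Gaussian likelihood this is Σ_i ∇θ y_i ∇θ y_iᵀ / β² (the
Gauss–Newton form), plus the prior precision I/α².  On linear-in-parameters
models it reproduces the closed-form Bayesian linear-regression precision
XᵀX/β² + I/α² exactly, which is the validation axis for the whole pipeline.
The covariance is the Moore–Penrose pseudoinverse of the (often singular,
overparameterized) Fisher matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dynamics import ODEField, TrajectoryBatch, integrate_batch, integrate_batch_vjp
from .objective import PriorSpec, RegressionData, log_prior

__all__ = [
    "FisherMatrix",
    "GaussianPosterior",
    "fisher_information",
    "laplace_posterior",
    "observation_jacobian",
]

PINV_PARAM_CEILING = 50_000


class ResourceError(RuntimeError):
    pass


@dataclass
class FisherMatrix:
    matrix: np.ndarray
    mode: str  # "gradient" | "hessian" | "gradient-diagonal"
    rank: int

    def __post_init__(self):
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8 * (1 + np.abs(self.matrix).max())):
            raise ValueError("Fisher matrix must be symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)


@dataclass
class GaussianPosterior:
    """Parameter posterior N(mean, cov).  ``diagonal`` marks mean-field
    sources whose covariance carries no cross terms."""

    mean: np.ndarray
    cov: np.ndarray
    diagonal: bool = False

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim == 1:  # variance vector
            self.cov = np.diag(self.cov)
            self.diagonal = True
        scale = 1 + np.abs(self.cov).max()
        if not np.allclose(self.cov, self.cov.T, atol=1e-10 * scale):
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def n_params(self) -> int:
        return self.mean.size

    def sample(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        if self.diagonal:
            sd = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))
            return self.mean + rng.standard_normal((n_samples, self.n_params)) * sd
        # eigh-based factor tolerates the PSD-but-singular covariances that
        # pseudoinverted Fisher matrices produce
        w, V = np.linalg.eigh(self.cov)
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)
        return self.mean + rng.standard_normal((n_samples, self.n_params)) @ L.T

    def save(self, path_prefix: str) -> None:
        np.savez_compressed(path_prefix + ".npz", mean=self.mean, cov=self.cov)
        with open(path_prefix + ".json", "w") as fh:
            json.dump(
                {
                    "n_params": int(self.n_params),
                    "diagonal": bool(self.diagonal),
                    "layout": "flat parameter vector: per layer W (C order) then b",
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path_prefix: str) -> "GaussianPosterior":
        with np.load(path_prefix + ".npz") as z:
            mean, cov = z["mean"], z["cov"]
        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        return cls(mean, cov, diagonal=meta.get("diagonal", False))


def observation_jacobian(theta, data, model, substeps: int = 10) -> np.ndarray:
    """Jacobian of every scalar observation prediction w.r.t. theta,
    shape (n_observations, n_params).

    For trajectory batches the observations are all (window, time, dim)
    entries in batch order; the window-initial rows (no θ dependence) are
    exact zeros.
    """
    theta = np.asarray(theta, dtype=float)
    if isinstance(data, TrajectoryBatch):
        field: ODEField = model
        N, L = data.times.shape
        d = data.targets.shape[2]
        _, cache = integrate_batch(field, theta, data.y0, data.times, substeps,
                                   want_cache=True)
        J = np.zeros((N, L, d, theta.size))
        for l in range(1, L):
            for k in range(d):
                G = np.zeros((N, L, d))
                G[:, l, k] = 1.0
                _, g = integrate_batch_vjp(field, theta, cache, G, substeps,
                                           per_sample=True)
                J[:, l, k, :] = g
        return J.reshape(N * L * d, theta.size)
    X, Y = data.X, data.Y
    n, n_out = Y.shape
    rows = np.zeros((n, n_out, theta.size))
    for k in range(n_out):
        G = np.zeros((n, n_out))
        G[:, k] = 1.0
        rows[:, k, :] = model.vjp(theta, X, G, per_sample=True)
    return rows.reshape(n * n_out, theta.size)


def _log_joint_of_theta(theta, data, model, beta2, prior, substeps):
    if isinstance(data, TrajectoryBatch):
        pred = integrate_batch(model, theta, data.y0, data.times, substeps)
        resid = pred - data.targets
    else:
        resid = model.predict(theta, data.X) - data.Y
    return -0.5 / beta2 * float(np.sum(resid**2)) + log_prior(theta, prior)


def _grad_log_joint(theta, data, model, beta2, prior, substeps):
    if isinstance(data, TrajectoryBatch):
        _, cache = integrate_batch(model, theta, data.y0, data.times, substeps,
                                   want_cache=True)
        pred = integrate_batch(model, theta, data.y0, data.times, substeps)
        _, g = integrate_batch_vjp(model, theta, cache, (pred - data.targets) / beta2,
                                   substeps)
    else:
        resid = model.predict(theta, data.X) - data.Y
        g = model.vjp(theta, data.X, resid / beta2)
    return -g - theta / prior.alpha**2


def fisher_information(
    theta_star,
    data,
    model,
    beta2: float,
    prior: PriorSpec = PriorSpec(),
    mode: str = "gradient",
    substeps: int = 10,
    diagonal_only: bool = False,
    hessian_eps: float = 1e-5,
) -> FisherMatrix:
    """Fisher information of the log-joint at the MAP.

    mode="gradient" (default): Gauss–Newton sum of per-observation score
    outer products with β² reinstated, plus the prior precision.
    mode="hessian": negated Hessian of the log-joint, by central finite
    differences of the analytic gradient — retained as a cross-check that is
    only practical for small parameter counts.
    ``diagonal_only`` keeps just the diagonal (the cheap fallback for models
    too large to pseudoinvert).
    """
    theta_star = np.asarray(theta_star, dtype=float)
    if beta2 <= 0:
        raise ValueError("beta2 must be > 0 (use estimate_noise_variance)")
    p = theta_star.size
    if mode == "gradient":
        J = observation_jacobian(theta_star, data, model, substeps)
        if not np.all(np.isfinite(J)):
            bad = int(np.where(~np.all(np.isfinite(J), axis=1))[0][0])
            raise FloatingPointError(f"non-finite gradient for observation {bad}")
        if diagonal_only:
            I = np.diag(np.sum(J**2, axis=0) / beta2 + 1.0 / prior.alpha**2)
            mode = "gradient-diagonal"
        else:
            I = J.T @ J / beta2 + np.eye(p) / prior.alpha**2
    elif mode == "hessian":
        H = np.zeros((p, p))
        for i in range(p):
            e = np.zeros(p)
            e[i] = hessian_eps
            gp = _grad_log_joint(theta_star + e, data, model, beta2, prior, substeps)
            gm = _grad_log_joint(theta_star - e, data, model, beta2, prior, substeps)
            H[i] = (gp - gm) / (2 * hessian_eps)
        I = -0.5 * (H + H.T)
    else:
        raise ValueError(f"unknown Fisher mode {mode!r}")
    I = 0.5 * (I + I.T)
    rank = int(np.linalg.matrix_rank(I, hermitian=True))
    return FisherMatrix(I, mode, rank)


def laplace_posterior(
    theta_star, fisher: FisherMatrix, rcond: float = 1e-10
) -> GaussianPosterior:
    """Posterior N(θ*, I_θ⁺): Moore–Penrose pseudoinverse of the Fisher
    matrix with singular values below ``rcond``·σ_max truncated."""
    theta_star = np.asarray(theta_star, dtype=float)
    if theta_star.size > PINV_PARAM_CEILING:
        raise ResourceError(
            f"{theta_star.size} parameters exceeds the pseudoinverse ceiling "
            f"({PINV_PARAM_CEILING})"
        )
    cov = np.linalg.pinv(fisher.matrix, rcond=rcond, hermitian=True)
    return GaussianPosterior(theta_star, cov)
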