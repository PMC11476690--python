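"""Log-joint density and MAP training of π-net parameters.

The training objective follows the Gaussian-noise log-joint: with the noise
variance β² unknown during training its constant 1/(2β²) factor is dropped,
so MAP training maximizes −Σ(y_pred − y_known)² + log-prior.  β² is estimated
afterwards from the residuals at the optimum and reinstated for every
posterior computation (Laplace, MCMC, VI all consume the full log-joint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ODEField, TrajectoryBatch, integrate_batch, integrate_batch_vjp
from .polynet import (
    ConfigurationError,
    PiNetConfig,
    PiNetParams,
    count_parameters,
    init_params,
    pinet_forward_cached,
    pinet_vjp,
)

__all__ = [
    "PriorSpec",
    "NoiseSpec",
    "MapResult",
    "RegressionData",
    "PiNetRegression",
    "LinearModel",
    "OptimizerSettings",
    "log_likelihood",
    "log_prior",
    "log_joint",
    "estimate_noise_variance",
    "train_map",
    "adam",
]


@dataclass(frozen=True)
class PriorSpec:
    """Zero-mean isotropic Gaussian prior on all network parameters.

    ``alpha`` is the prior standard deviation; the default 1e5 is a
    noninformative choice under which the prior is numerically negligible
    during point estimation but keeps every posterior proper.
    """

    alpha: float = 1e5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ConfigurationError("prior alpha must be > 0")


@dataclass
class NoiseSpec:
    beta2: float
    status: str = "assumed"  # or "estimated-at-MAP"

    def __post_init__(self):
        if self.beta2 < 0:
            raise ConfigurationError("beta2 must be >= 0")


def log_likelihood(y_pred, y_known, beta2: float) -> float:
    """Gaussian log-likelihood −Σ(y_pred − y_known)²/(2β²), up to the
    additive normalization constant."""
    if beta2 <= 0:
        raise ValueError("beta2 must be > 0")
    y_pred = np.asarray(y_pred, dtype=float)
    y_known = np.asarray(y_known, dtype=float)
    if y_pred.shape != y_known.shape:
        raise ConfigurationError("y_pred and y_known must have the same shape")
    return float(-0.5 / beta2 * np.sum((y_pred - y_known) ** 2))


def log_prior(theta, prior: PriorSpec) -> float:
    """−θᵀθ / (2α²)."""
    theta = np.asarray(theta, dtype=float)
    return float(-0.5 * np.sum(theta**2) / prior.alpha**2)


def log_joint(y_pred, y_known, theta, beta2: float, prior: PriorSpec) -> float:
    """Log-likelihood plus log-prior (equality up to an additive constant)."""
    return log_likelihood(y_pred, y_known, beta2) + log_prior(theta, prior)


def estimate_noise_variance(residuals) -> float:
    """Sample variance (denominator n, centered at the residual mean) of the
    pooled residual vector y_pred − y_known at the MAP point."""
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("need at least 2 residuals to estimate beta2")
    return float(np.var(r))


# ---------------------------------------------------------------------------
# models and data for MAP fitting


@dataclass
class RegressionData:
    """Plain (input, observation) pairs for a π-net regression fit."""

    X: np.ndarray  # (n, state_dim)
    Y: np.ndarray  # (n, output_dim)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.shape[0] != self.Y.shape[0]:
            raise ConfigurationError("X and Y must have the same number of rows")


class PiNetRegression:
    """Regression model y = net(x; theta) with the same vjp contract used by
    the ODE training path."""

    def __init__(self, config: PiNetConfig):
        self.config = config
        self.n_params = count_parameters(config)

    def predict(self, theta, X):
        params = PiNetParams.from_vector(np.asarray(theta, dtype=float), self.config)
        out, _ = pinet_forward_cached(params, self.config, X)
        return out

    def vjp(self, theta, X, G, per_sample: bool = False):
        params = PiNetParams.from_vector(np.asarray(theta, dtype=float), self.config)
        _, cache = pinet_forward_cached(params, self.config, X)
        _, gtheta = pinet_vjp(params, self.config, cache, G, per_sample=per_sample)
        return gtheta

    def init(self, seed: int):
        return init_params(self.config, seed).to_vector()


class LinearModel:
    """y = X @ theta — a linear-in-parameters model used to validate MAP and
    Laplace against their closed forms."""

    def __init__(self, n_params: int, n_outputs: int = 1):
        if n_outputs != 1:
            raise ConfigurationError("LinearModel supports scalar outputs")
        self.n_params = n_params

    def predict(self, theta, X):
        return (X @ np.asarray(theta, dtype=float))[:, None]

    def vjp(self, theta, X, G, per_sample: bool = False):
        G = G[:, 0]
        if per_sample:
            return X * G[:, None]
        return X.T @ G

    def init(self, seed: int):
        return np.zeros(self.n_params)


@dataclass
class OptimizerSettings:
    """Adam settings for MAP training.

    ``epochs`` defaults to 10 000 for neural-ODE fits and 5 000 for
    regression fits when left as None.  ``lr_decay="cosine"`` anneals the
    learning rate to ``lr_min`` over the run; ``"none"`` keeps it constant.
    """

    learning_rate: float = 1e-3
    epochs: int | None = None
    substeps: int = 10
    include_prior: bool = True
    lr_decay: str = "cosine"
    lr_min: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    grad_clip: float | None = 1e4  # global-norm clip; guards the integrator
                                   # against transient parameter overshoots


@dataclass
class MapResult:
    theta_star: np.ndarray
    objective: float
    trace: np.ndarray  # objective (−SSE + log-prior) per epoch
    beta2: float
    noise: NoiseSpec = field(init=False)

    def __post_init__(self):
        if not np.all(np.isfinite(self.trace)):
            raise RuntimeError("non-finite objective trace")
        self.noise = NoiseSpec(self.beta2, status="estimated-at-MAP")

    def to_json_dict(self) -> dict:
        return {
            "theta_star": self.theta_star.tolist(),
            "objective": self.objective,
            "beta2": self.beta2,
        }


def adam(grad_fn, theta0, epochs, settings: OptimizerSettings, callback=None):
    """Minimize via Adam; ``grad_fn(theta) -> (loss, grad)``."""
    theta = np.asarray(theta0, dtype=float).copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    losses = np.empty(epochs)
    for t in range(epochs):
        loss, g = grad_fn(theta)
        if not np.isfinite(loss):
            raise RuntimeError(f"NaN/inf objective at epoch {t}")
        losses[t] = loss
        if settings.grad_clip is not None:
            gn = float(np.linalg.norm(g))
            if gn > settings.grad_clip:
                g = g * (settings.grad_clip / gn)
        if settings.lr_decay == "cosine":
            lr = settings.lr_min + 0.5 * (settings.learning_rate - settings.lr_min) * (
                1 + np.cos(np.pi * t / max(epochs - 1, 1))
            )
        else:
            lr = settings.learning_rate
        m = settings.beta1 * m + (1 - settings.beta1) * g
        v = settings.beta2 * v + (1 - settings.beta2) * g**2
        mhat = m / (1 - settings.beta1 ** (t + 1))
        vhat = v / (1 - settings.beta2 ** (t + 1))
        theta -= lr * mhat / (np.sqrt(vhat) + settings.eps)
        if callback is not None:
            callback(t, theta, loss)
    return theta, losses


def _ode_loss(field: ODEField, batches: TrajectoryBatch, substeps: int):
    w = batches.weights

    def fn(theta):
        states, cache = integrate_batch(
            field, theta, batches.y0, batches.times, substeps, want_cache=True
        )
        resid = states - batches.targets
        if w is None:
            sse = float(np.sum(resid**2))
            cot = 2.0 * resid
        else:
            sse = float(np.sum(w[:, None, None] * resid**2))
            cot = 2.0 * w[:, None, None] * resid
        _, g = integrate_batch_vjp(field, theta, cache, cot, substeps)
        return sse, g

    return fn


def _regression_loss(model, data: RegressionData):
    def fn(theta):
        resid = model.predict(theta, data.X) - data.Y
        sse = float(np.sum(resid**2))
        g = model.vjp(theta, data.X, 2.0 * resid)
        return sse, g

    return fn


def map_residuals(model_or_field, data, theta, substeps: int = 10) -> np.ndarray:
    """Pooled residual vector y_pred − y_known at ``theta``."""
    if isinstance(data, TrajectoryBatch):
        states = integrate_batch(model_or_field, theta, data.y0, data.times, substeps)
        return (states - data.targets).ravel()
    return (model_or_field.predict(theta, data.X) - data.Y).ravel()


def train_map(
    data,
    model,
    prior: PriorSpec = PriorSpec(),
    settings: OptimizerSettings | None = None,
    seed: int = 0,
    theta0: np.ndarray | None = None,
) -> MapResult:
    """MAP-fit a model by Adam on −SSE + log-prior.

    ``data`` is a :class:`TrajectoryBatch` (neural-ODE fit: every window's
    initial-value problem is integrated simultaneously each epoch) or a
    :class:`RegressionData`.  ``model`` is correspondingly an
    :class:`~pinets.dynamics.ODEField` or a regression model.  β² is
    estimated from the pooled residuals at the optimum.
    """
    settings = settings or OptimizerSettings()
    is_ode = isinstance(data, TrajectoryBatch)
    if is_ode:
        if data.n_windows == 0:
            raise ConfigurationError("empty batch")
        loss_fn = _ode_loss(model, data, settings.substeps)
    else:
        loss_fn = _regression_loss(model, data)
    epochs = settings.epochs if settings.epochs is not None else (10_000 if is_ode else 5_000)

    if theta0 is None:
        theta0 = model.init(seed) if hasattr(model, "init") else np.zeros(model.n_params)

    lam = 1.0 / prior.alpha**2 if settings.include_prior else 0.0

    def grad_fn(theta):
        sse, g = loss_fn(theta)
        return sse + 0.5 * lam * float(np.sum(theta**2)), g + lam * theta

    theta_star, losses = adam(grad_fn, theta0, epochs, settings)
    resid = map_residuals(model, data, theta_star, settings.substeps)
    beta2 = estimate_noise_variance(resid)
    final_sse, _ = loss_fn(theta_star)
    objective = -final_sse + log_prior(theta_star, prior)
    return MapResult(theta_star, objective, -losses, beta2)
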