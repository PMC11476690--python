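"""Mean-field Gaussian variational inference.

The variational family is a fully factorized Gaussian q(θ) = Π N(μ_i, σ_i²);
the objective is the evidence lower bound

    ELBO = E_q[log p(D|θ)] − KL(q ‖ prior),

with the expectation estimated by Monte Carlo under the reparameterization
θ = μ + σ ε (so the estimate is differentiable in μ and log σ) and the KL
between diagonal Gaussians computed in closed form.  Means are initialized
from the MAP point estimate — obtaining a point estimate first and seeding
the variational mean with it is what makes this family trainable in
practice — and log-standard-deviations start small.  A full-covariance
Gaussian family is deliberately not offered (keeping a learned covariance
positive semidefinite is not worth the trouble next to the mean-field fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TrajectoryBatch, integrate_batch, integrate_batch_vjp
from .laplace import GaussianPosterior
from .objective import PriorSpec

__all__ = [
    "MeanFieldGaussian",
    "VISettings",
    "elbo_estimate",
    "kl_diag_gaussian_prior",
    "fit_vi",
]


@dataclass
class MeanFieldGaussian:
    """Per-parameter mean and log-standard-deviation."""

    mu: np.ndarray
    log_sd: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.log_sd = np.asarray(self.log_sd, dtype=float).ravel()
        if self.mu.shape != self.log_sd.shape:
            raise ValueError("mu and log_sd must have the same shape")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.log_sd))):
            raise ValueError("non-finite variational parameters")

    @property
    def sd(self) -> np.ndarray:
        return np.exp(self.log_sd)

    def to_posterior(self) -> GaussianPosterior:
        return GaussianPosterior(self.mu, np.diag(self.sd**2), diagonal=True)


@dataclass
class VISettings:
    learning_rate: float = 1e-2
    iterations: int = 20_000
    n_mc: int = 1000          # draws for the reported ELBO estimate
    grad_samples: int = 32    # draws per gradient step (reparameterized)
    seed: int = 0
    init_log_sd: float = np.log(1e-3)
    lr_decay: str = "cosine"
    lr_min: float = 1e-4

    def __post_init__(self):
        if self.n_mc < 1 or self.grad_samples < 1:
            raise ValueError("sample counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


def kl_diag_gaussian_prior(q: MeanFieldGaussian, prior: PriorSpec) -> float:
    """Closed-form KL(q ‖ N(0, α²I)) for diagonal q."""
    a2 = prior.alpha**2
    s2 = q.sd**2
    return float(np.sum(0.5 * np.log(a2 / s2) + (s2 + q.mu**2) / (2 * a2) - 0.5))


def elbo_estimate(
    q: MeanFieldGaussian,
    loglik,
    prior: PriorSpec,
    n_mc: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo ELBO: average of ``loglik(θ)`` over ``n_mc``
    reparameterized draws from q, minus the closed-form KL term."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_mc, q.mu.size))
    thetas = q.mu + q.sd * eps
    vals = np.array([loglik(th) for th in thetas], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite log-likelihood for a variational draw")
    return float(vals.mean()) - kl_diag_gaussian_prior(q, prior)


def _loglik_and_grad_factory(data, model, beta2: float, substeps: int):
    if isinstance(data, TrajectoryBatch):
        def fn(theta):
            states, cache = integrate_batch(model, theta, data.y0, data.times,
                                            substeps, want_cache=True)
            resid = states - data.targets
            ll = -0.5 / beta2 * float(np.sum(resid**2))
            _, g = integrate_batch_vjp(model, theta, cache, resid / beta2, substeps)
            return ll, -g
    else:
        def fn(theta):
            resid = model.predict(theta, data.X) - data.Y
            ll = -0.5 / beta2 * float(np.sum(resid**2))
            g = model.vjp(theta, data.X, resid / beta2)
            return ll, -g
    return fn


def fit_vi(
    data,
    model,
    beta2: float,
    prior: PriorSpec = PriorSpec(),
    settings: VISettings = VISettings(),
    theta_init: np.ndarray | None = None,
    substeps: int = 10,
):
    """Maximize the ELBO over a mean-field Gaussian by Adam with
    reparameterization gradients.

    ``data``/``model`` follow the same contract as MAP training (a
    :class:`TrajectoryBatch` with an ODE field, or regression data with a
    regression model); ``beta2`` is the observation-noise variance (use the
    MAP estimate).  ``theta_init`` seeds the variational mean (the MAP
    parameters); when None the model's own initializer is used.

    Returns ``(posterior, elbo_trace)`` with a diagonal
    :class:`~pinets.laplace.GaussianPosterior`.
    """
    if beta2 <= 0:
        raise ValueError("beta2 must be > 0")
    rng = np.random.default_rng(settings.seed)
    llg = _loglik_and_grad_factory(data, model, beta2, substeps)
    if theta_init is None:
        theta_init = model.init(settings.seed) if hasattr(model, "init") else None
    if theta_init is None:
        raise ValueError("theta_init required for models without an initializer")
    mu = np.asarray(theta_init, dtype=float).copy()
    s = np.full(mu.size, settings.init_log_sd)
    a2 = prior.alpha**2

    # Adam state over the stacked (mu, log_sd) vector
    m = np.zeros(2 * mu.size)
    v = np.zeros(2 * mu.size)
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    trace = np.empty(settings.iterations)
    S = settings.grad_samples
    for t in range(settings.iterations):
        sd = np.exp(s)
        epsn = rng.standard_normal((S, mu.size))
        gmu = np.zeros_like(mu)
        gs = np.zeros_like(s)
        ll_sum = 0.0
        for k in range(S):
            theta = mu + sd * epsn[k]
            ll, g = llg(theta)
            ll_sum += ll
            gmu += g
            gs += g * sd * epsn[k]
        gmu /= S
        gs /= S
        # KL gradients (closed form)
        gmu -= mu / a2
        gs -= sd**2 / a2 - 1.0
        elbo = ll_sum / S - float(
            np.sum(0.5 * np.log(a2 / sd**2) + (sd**2 + mu**2) / (2 * a2) - 0.5)
        )
        if not np.isfinite(elbo):
            raise RuntimeError(f"non-finite ELBO at iteration {t}")
        trace[t] = elbo
        g_all = -np.concatenate([gmu, gs])  # minimize −ELBO
        if settings.lr_decay == "cosine":
            lr = settings.lr_min + 0.5 * (settings.learning_rate - settings.lr_min) * (
                1 + np.cos(np.pi * t / max(settings.iterations - 1, 1))
            )
        else:
            lr = settings.learning_rate
        m = b1 * m + (1 - b1) * g_all
        v = b2 * v + (1 - b2) * g_all**2
        mhat = m / (1 - b1 ** (t + 1))
        vhat = v / (1 - b2 ** (t + 1))
        step = lr * mhat / (np.sqrt(vhat) + eps_adam)
        mu -= step[: mu.size]
        s -= step[mu.size :]
    q = MeanFieldGaussian(mu, s)
    return q.to_posterior(), trace
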