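"""Gaussian-process pre-smoothing of noisy trajectories.

Heavily noisy observations cannot serve as initial conditions for the
training windows of a neural ODE; a GP regression fit of the pooled noisy
replicates supplies denoised window-start states instead.  The kernels on
offer are the ones that work for these systems: the periodic
(exp-sine-squared) kernel for sustained oscillators,

    k(t_i, t_j) = c² exp(−2 sin²(π d/p) / l²) + σ_GPR² δ_ij,

and the rational quadratic for decaying or chaotic trajectories,

    k(t_i, t_j) = c² (1 + d²/(2 α_rq l²))^(−α_rq) + σ_GPR² δ_ij,

plus RBF and Matérn.  Hyperparameters are set by maximizing the marginal
likelihood with multi-restart local optimization (scikit-learn backend);
``kernel_eval`` here is an independent implementation of the same formulas
used for direct checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as skk

from .dynamics import Trajectory

__all__ = ["KernelSpec", "SmootherFit", "kernel_eval", "fit_gpr", "initial_conditions"]

_VARIANTS = ("periodic", "rational-quadratic", "rbf", "matern")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and hyperparameters (all strictly positive).

    ``c2`` scales the kernel (constant-kernel factor), ``length_scale`` is
    l, ``periodicity`` p applies to the periodic variant, ``alpha_rq`` is
    the rational-quadratic scale mixture, and ``white_noise`` is the
    σ_GPR² variance added on the diagonal only.
    """

    variant: str = "rational-quadratic"
    c2: float = 1.0
    length_scale: float = 1.0
    periodicity: float = 1.0
    alpha_rq: float = 1.0
    white_noise: float = 1e-2
    nu: float = 1.5  # matern only

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown kernel variant {self.variant!r}")
        for name in ("c2", "length_scale", "periodicity", "alpha_rq", "white_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def kernel_eval(spec: KernelSpec, t_i: float, t_j: float, same_index: bool = False) -> float:
    """Evaluate the covariance between two scalar times.

    The white-noise term is added only when ``same_index`` is true (it lives
    on the Gram diagonal, not at coincident time values).
    """
    d = abs(float(t_i) - float(t_j))
    if spec.variant == "periodic":
        k = spec.c2 * np.exp(-2.0 * np.sin(np.pi * d / spec.periodicity) ** 2
                             / spec.length_scale**2)
    elif spec.variant == "rational-quadratic":
        k = spec.c2 * (1.0 + d**2 / (2.0 * spec.alpha_rq * spec.length_scale**2)
                       ) ** (-spec.alpha_rq)
    elif spec.variant == "rbf":
        k = spec.c2 * np.exp(-0.5 * d**2 / spec.length_scale**2)
    else:  # matern
        k = spec.c2 * skk.Matern(length_scale=spec.length_scale, nu=spec.nu)(
            np.array([[t_i]]), np.array([[t_j]]))[0, 0]
    if same_index:
        k += spec.white_noise
    return float(k)


def _sk_kernel(spec: KernelSpec, bounds=(1e-3, 1e3), ls_bounds=None):
    # a length scale below the sampling interval is indistinguishable from
    # white noise, so the fit bounds it by the data spacing
    ls_bounds = ls_bounds or bounds
    c = skk.ConstantKernel(spec.c2, constant_value_bounds=bounds)
    w = skk.WhiteKernel(spec.white_noise, noise_level_bounds=bounds)
    ls = max(spec.length_scale, ls_bounds[0])
    if spec.variant == "periodic":
        base = skk.ExpSineSquared(
            length_scale=ls, periodicity=spec.periodicity,
            length_scale_bounds=bounds, periodicity_bounds=bounds)
    elif spec.variant == "rational-quadratic":
        base = skk.RationalQuadratic(
            length_scale=ls, alpha=spec.alpha_rq,
            length_scale_bounds=ls_bounds, alpha_bounds=bounds)
    elif spec.variant == "rbf":
        base = skk.RBF(length_scale=ls, length_scale_bounds=ls_bounds)
    else:
        base = skk.Matern(length_scale=ls, nu=spec.nu,
                          length_scale_bounds=ls_bounds)
    return c * base + w


@dataclass
class SmootherFit:
    """One independent GP per state dimension, fit to pooled noisy data."""

    gps: list
    t_min: float
    t_max: float
    spec: KernelSpec
    log_marginal_likelihood: float
    fitted_kernels: list = field(default_factory=list)

    @property
    def state_dim(self) -> int:
        return len(self.gps)

    def predict(self, times) -> np.ndarray:
        """Predictive mean at the requested times, (n, state_dim).

        The smoother interpolates; requests outside the training span raise.
        """
        t = np.asarray(times, dtype=float).ravel()
        tol = 1e-9 * (1 + abs(self.t_max))
        if t.min() < self.t_min - tol or t.max() > self.t_max + tol:
            raise ValueError(
                f"requested times outside the training span "
                f"[{self.t_min:g}, {self.t_max:g}]; the smoother does not extrapolate"
            )
        cols = [gp.predict(t[:, None]) for gp in self.gps]
        return np.stack(cols, axis=1)

    def smoothed(self, grid) -> Trajectory:
        return Trajectory(np.asarray(grid, dtype=float), self.predict(grid))


def fit_gpr(
    times,
    observations,
    spec: KernelSpec = KernelSpec(),
    restarts: int = 5,
    seed: int = 0,
    max_points: int = 600,
) -> SmootherFit:
    """Fit one GP per state dimension by marginal-likelihood maximization.

    ``times`` (n,) and ``observations`` (n, state_dim) may pool several
    replicate trajectories (rows need not be sorted or unique in time).
    Exact GP inference is cubic in n, so pooled sets larger than
    ``max_points`` are uniformly subsampled before fitting; prediction is
    unaffected.  ``restarts`` extra optimizer starts guard against bad local
    optima; fixed seed gives identical fits.
    """
    t = np.asarray(times, dtype=float).ravel()
    Y = np.atleast_2d(np.asarray(observations, dtype=float))
    if Y.shape[0] != t.size:
        Y = Y.T
    if Y.shape[0] != t.size:
        raise ValueError("observations do not align with times")
    if t.size < 5:
        raise ValueError("need at least 5 points per state dimension")
    if t.size > max_points:
        idx = np.linspace(0, t.size - 1, max_points).astype(int)
        t, Y = t[idx], Y[idx]
    uniq = np.unique(t)
    dt = float(np.median(np.diff(uniq))) if uniq.size > 1 else 1e-3
    ls_bounds = (max(1e-3, 1.5 * dt), 1e3)
    gps, lml, fitted = [], 0.0, []
    for dim in range(Y.shape[1]):
        gp = GaussianProcessRegressor(
            kernel=_sk_kernel(spec, ls_bounds=ls_bounds),
            n_restarts_optimizer=restarts,
            normalize_y=True,
            random_state=seed + dim,
        )
        gp.fit(t[:, None], Y[:, dim])
        gps.append(gp)
        lml += float(gp.log_marginal_likelihood_value_)
        fitted.append(gp.kernel_)
    return SmootherFit(gps, float(t.min()), float(t.max()), spec, lml, fitted)


def initial_conditions(fit: SmootherFit, start_times) -> np.ndarray:
    """Predictive mean states at each window start time (interpolation
    only)."""
    return fit.predict(start_times)
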