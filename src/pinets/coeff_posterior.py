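"""Posterior distributions for expanded polynomial coefficients.

Parameter posteriors (Gaussian from Laplace/VI, or MCMC draws) are pushed
forward to coefficient posteriors by Monte Carlo: draw parameter vectors,
symbolically expand each draw, and summarize the resulting coefficient
samples with equal-tailed quantile credible intervals, kernel density
estimates, and posterior-predictive trajectory bands.  Analytic propagation
through Gaussian product/sum rules is deliberately not offered: the weights
and biases are dependent, which is exactly why sampling is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .laplace import GaussianPosterior
from .polynet import ConfigurationError, PiNetConfig, count_parameters, expand_batch, monomial_exponents, PolynomialForm, _var_names

__all__ = [
    "CoefficientSamples",
    "PredictiveBand",
    "DensitySummary",
    "sample_coefficients",
    "quantile_interval",
    "posterior_predictive",
    "density_summary",
]


@dataclass
class CoefficientSamples:
    """Monte-Carlo draws of expanded polynomial coefficients.

    ``samples`` has shape (n_samples, output_dim, n_monomials); column m of
    the last axis corresponds to ``exponents[m]`` / ``labels[m]``.
    """

    samples: np.ndarray
    exponents: list[tuple[int, ...]]
    labels: list[str]
    var_names: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, exponent: tuple[int, ...], output: int = 0) -> np.ndarray:
        return self.samples[:, output, self.exponents.index(tuple(exponent))]

    def mean_form(self) -> PolynomialForm:
        return PolynomialForm(self.exponents, self.samples.mean(axis=0), self.var_names)

    def summary(self, levels=(0.95,)) -> dict:
        """Mean, SD and quantile intervals per monomial per output."""
        out = {}
        nout = self.samples.shape[1]
        for i in range(nout):
            rows = {}
            for m, lab in enumerate(self.labels):
                col = self.samples[:, i, m]
                entry = {"mean": float(col.mean()), "sd": float(col.std())}
                for lv in levels:
                    lo, hi = quantile_interval(col, lv)
                    entry[f"ci{lv:g}"] = [lo, hi]
                rows[lab] = entry
            out[f"output_{i}"] = rows
        return out

    def to_frame(self, output: int = 0):
        import pandas as pd

        return pd.DataFrame(self.samples[:, output, :], columns=self.labels)


def _chain_draws(posterior) -> np.ndarray | None:
    # ChainSamples duck-typed to avoid an import cycle with mcmc
    draws = getattr(posterior, "draws", None)
    return None if draws is None else np.asarray(draws, dtype=float)


def sample_coefficients(
    posterior,
    config: PiNetConfig,
    n_samples: int = 2000,
    seed: int = 0,
) -> CoefficientSamples:
    """Draw parameter vectors from ``posterior`` (a GaussianPosterior or a
    ChainSamples) and expand each draw into polynomial coefficients.

    Gaussian posteriors are sampled natively; chain posteriors reuse their
    stored draws, with ``n_samples`` capped at the chain length.
    """
    rng = np.random.default_rng(seed)
    draws = _chain_draws(posterior)
    if draws is None:
        if not isinstance(posterior, GaussianPosterior):
            raise ConfigurationError("posterior must be GaussianPosterior or ChainSamples")
        if posterior.n_params != count_parameters(config):
            raise ConfigurationError(
                f"posterior has {posterior.n_params} parameters, config needs "
                f"{count_parameters(config)}"
            )
        thetas = posterior.sample(n_samples, rng)
    else:
        if draws.shape[1] != count_parameters(config):
            raise ConfigurationError("chain parameter layout does not match config")
        take = min(n_samples, draws.shape[0])
        thetas = draws[-take:]
    coeffs = expand_batch(thetas, config)
    exps = monomial_exponents(config.state_dim, config.degree)
    names = _var_names(config.state_dim)
    form = PolynomialForm(exps, coeffs[0], names)
    labels = [form.monomial_label(e) for e in exps]
    return CoefficientSamples(coeffs, exps, labels, names)


def quantile_interval(samples, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval: the (1−level)/2 and 1−(1−level)/2
    empirical quantiles."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    s = np.asarray(samples, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    tail = (1.0 - level) / 2.0
    return float(np.quantile(s, tail)), float(np.quantile(s, 1.0 - tail))


@dataclass
class PredictiveBand:
    """Posterior-predictive mean trajectory with nested credible envelopes.

    ``lower``/``upper`` map level -> (n_times, state_dim) arrays.
    """

    times: np.ndarray
    mean: np.ndarray
    lower: dict[float, np.ndarray]
    upper: dict[float, np.ndarray]
    n_excluded: int = 0

    def to_frame(self, state_names=None):
        import pandas as pd

        d = self.mean.shape[1]
        names = state_names or [f"y{i}" for i in range(d)]
        cols = {"t": self.times}
        for i, nm in enumerate(names):
            cols[f"{nm}_mean"] = self.mean[:, i]
            for lv in sorted(self.lower):
                cols[f"{nm}_lo{lv:g}"] = self.lower[lv][:, i]
                cols[f"{nm}_hi{lv:g}"] = self.upper[lv][:, i]
        return pd.DataFrame(cols)


def _integrate_coeff_draws(coeffs, exponents, y0, grid, substeps, known=None):
    """Fixed-step RK4(F) integration of one trajectory per coefficient draw.

    Each draw's right-hand side is its expanded polynomial, evaluated from
    the coefficient array directly (exactly equivalent to the network, and
    vectorizable across draws).  Returns (S, n_times, d) with NaN rows for
    draws that diverged.
    """
    from .dynamics import _A, _B4, _C, _N_STAGES

    S = coeffs.shape[0]
    d = y0.size
    E = np.array(exponents, dtype=float)  # (M, d)

    def rhs(t, Y):  # Y: (S, d)
        with np.errstate(all="ignore"):
            powers = np.prod(Y[:, None, :] ** E[None, :, :], axis=2)  # (S, M)
            out = np.einsum("som,sm->so", coeffs, powers)
        if known is not None:
            out = out + known.eval(t, Y, None)
        return out

    grid = np.asarray(grid, dtype=float)
    Y = np.tile(np.asarray(y0, dtype=float)[None, :], (S, 1))
    alive = np.ones(S, dtype=bool)
    states = np.full((S, grid.size, d), np.nan)
    states[:, 0] = Y
    for k in range(grid.size - 1):
        h = (grid[k + 1] - grid[k]) / substeps
        t = grid[k]
        for _ in range(substeps):
            with np.errstate(all="ignore"):
                ks = []
                for i in range(_N_STAGES):
                    yi = Y
                    for j, a in enumerate(_A[i]):
                        if a != 0.0:
                            yi = yi + (h * a) * ks[j]
                    ks.append(rhs(t + _C[i] * h, yi))
                for i in range(_N_STAGES):
                    if _B4[i] != 0.0:
                        Y = Y + (h * _B4[i]) * ks[i]
            t += h
            bad = ~np.all(np.isfinite(Y), axis=1)
            if np.any(bad & alive):
                alive &= ~bad
                Y = np.where(alive[:, None], Y, 0.0)
        states[alive, k + 1] = Y[alive]
    states[~alive] = np.nan
    return states, int(np.sum(~alive))


def posterior_predictive(
    posterior,
    config: PiNetConfig,
    y0=None,
    grid=None,
    x_grid=None,
    levels=(0.95, 0.997),
    n_samples: int = 2000,
    seed: int = 0,
    substeps: int = 10,
    known=None,
) -> PredictiveBand:
    """Posterior-predictive trajectories (or regression curves) with
    quantile credible bands.

    For each posterior draw the implied polynomial model is evaluated: on
    ``x_grid`` directly for a regression net, or integrated from ``y0`` over
    ``grid`` for an ODE net (with the known-field augmentation added when
    present).  The band at each level is the pointwise equal-tailed quantile
    interval; draws whose integration diverges are excluded with a count, and
    more than 10% exclusions is an error.
    """
    for lv in levels:
        if not 0 < lv < 1:
            raise ValueError("levels must be in (0, 1)")
    cs = sample_coefficients(posterior, config, n_samples, seed)
    coeffs = cs.samples
    if x_grid is not None:
        xg = np.atleast_2d(np.asarray(x_grid, dtype=float).T).T
        if xg.ndim == 1:
            xg = xg[:, None]
        E = np.array(cs.exponents, dtype=float)
        powers = np.prod(xg[:, None, :] ** E[None, :, :], axis=2)  # (n, M)
        vals = np.einsum("som,nm->sno", coeffs, powers)
        times = np.asarray(x_grid, dtype=float).ravel()
        n_excluded = 0
    else:
        if y0 is None or grid is None:
            raise ConfigurationError("ODE prediction needs y0 and grid")
        y0 = np.asarray(y0, dtype=float).ravel()
        vals, n_excluded = _integrate_coeff_draws(
            coeffs, cs.exponents, y0, grid, substeps, known=known
        )
        if n_excluded > 0.10 * coeffs.shape[0]:
            raise RuntimeError(
                f"{n_excluded}/{coeffs.shape[0]} posterior draws diverged during "
                "integration"
            )
        vals = vals[np.all(np.isfinite(vals.reshape(vals.shape[0], -1)), axis=1)]
        times = np.asarray(grid, dtype=float)
    mean = vals.mean(axis=0)
    lower, upper = {}, {}
    for lv in sorted(levels):
        tail = (1 - lv) / 2
        lower[lv] = np.quantile(vals, tail, axis=0)
        upper[lv] = np.quantile(vals, 1 - tail, axis=0)
    return PredictiveBand(times, mean, lower, upper, n_excluded)


@dataclass
class DensitySummary:
    grid: np.ndarray
    density: np.ndarray | None
    point_mass: float | None = None


def density_summary(samples, grid=None, n_grid: int = 256) -> DensitySummary:
    """Gaussian kernel density estimate (Scott's rule) of coefficient samples.

    Zero-variance samples yield a point-mass flag instead of a density.
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    if np.std(s) == 0.0:
        g = np.asarray(grid) if grid is not None else np.array([s[0]])
        return DensitySummary(g, None, point_mass=float(s[0]))
    if grid is None:
        lo = s.mean() - 6 * s.std()
        hi = s.mean() + 6 * s.std()
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    kde = gaussian_kde(s, bw_method="scott")
    return DensitySummary(grid, kde(grid))
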