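"""Hamiltonian Monte Carlo and the No-U-Turn Sampler, with the Geweke
convergence diagnostic.

Both samplers target the posterior ∝ exp(log-joint) through a user-supplied
callable returning the log-density and its gradient.  NUTS self-tunes the
step size by dual averaging during warmup (target acceptance 0.9) and
estimates a diagonal mass matrix from the warmup draws; plain HMC uses the
user-fixed step size ϵ and leapfrog count L with a Metropolis–Hastings
correction.  Warmup draws are discarded from the returned chain.

The Geweke statistic compares the means of an early and a late chain
segment:

    T = (X̄1 − X̄2) / sqrt(s1²/n1 + s2²/n2)

with segment 1 the first 10% and segment 2 the last 50% of the post-burn-in
chain by default; |T| ≤ 1.964 is the level-0.05 pass criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HMCSettings",
    "ChainSamples",
    "GewekeResult",
    "sample_hmc",
    "sample_nuts",
    "geweke",
    "geweke_coefficients",
    "DegenerateChainError",
]

_MAX_TREE_DEPTH = 10
_DIVERGENCE_THRESHOLD = 1000.0


class DegenerateChainError(RuntimeError):
    pass


@dataclass
class HMCSettings:
    step_size: float = 0.1       # ϵ (HMC; NUTS warmup overwrites it)
    n_leapfrog: int = 10         # L (HMC only)
    warmup: int = 1000
    samples: int = 1000
    target_accept: float = 0.9   # NUTS dual-averaging target; the
                                 # conservative value keeps the adapted step
                                 # clear of the divergence boundary
    max_tree_depth: int = _MAX_TREE_DEPTH
    inv_mass: np.ndarray | None = None  # diagonal inverse mass; a curvature
                                        # estimate (e.g. the Laplace posterior
                                        # variances) preconditions the sampler

    def __post_init__(self):
        if self.step_size <= 0 or self.n_leapfrog < 1:
            raise ValueError("need step_size > 0 and n_leapfrog >= 1")


@dataclass
class ChainSamples:
    draws: np.ndarray            # (n_samples, n_params), post-warmup
    accept_rate: float
    warmup: int
    divergences: int = 0
    warning: str | None = None
    step_size: float = np.nan

    def __post_init__(self):
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[0] == 0:
            raise ValueError("empty chain")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws")

    def to_frame(self, columns=None):
        import pandas as pd

        return pd.DataFrame(self.draws, columns=columns)


def _check_logjoint(logjoint, init):
    lp, g = logjoint(init)
    if not np.isfinite(lp) or not np.all(np.isfinite(g)):
        raise ValueError("log-joint is not finite at the initial state")
    return lp, g


def _leapfrog(logjoint, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    lp, grad = logjoint(theta)
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(np.sum(inv_mass * p**2))


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan defaults)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.t += 1
        w = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        wt = self.t ** (-self.kappa)
        self.log_eps_bar = wt * self.log_eps + (1 - wt) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _find_reasonable_eps(logjoint, theta, rng, inv_mass):
    eps = 1.0
    lp, grad = logjoint(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p, inv_mass)
    t1, p1, lp1, _ = _leapfrog(logjoint, theta, p, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        t1, p1, lp1, _ = _leapfrog(logjoint, theta, p, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def sample_hmc(
    logjoint,
    init: np.ndarray,
    settings: HMCSettings = HMCSettings(),
    seed: int = 0,
) -> ChainSamples:
    """Hamiltonian Monte Carlo with fixed step size ϵ and leapfrog count L.

    ``logjoint(theta) -> (log density, gradient)``.  Warmup iterations run
    the same transition and are discarded.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(init, dtype=float).copy()
    lp, grad = _check_logjoint(logjoint, theta)
    inv_mass = (np.ones(theta.size) if settings.inv_mass is None
                else np.asarray(settings.inv_mass, dtype=float))
    eps, L = settings.step_size, settings.n_leapfrog
    total = settings.warmup + settings.samples
    draws = np.empty((settings.samples, theta.size))
    n_accept = 0
    divergences = 0
    for it in range(total):
        p0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(p0, inv_mass)
        th, p, lp_new, g = theta, p0, lp, grad
        ok = True
        for _ in range(L):
            th, p, lp_new, g = _leapfrog(logjoint, th, p, g, eps, inv_mass)
            if not np.isfinite(lp_new):
                ok = False
                break
        if ok:
            h1 = lp_new - _kinetic(p, inv_mass)
            accept = min(1.0, np.exp(min(h1 - h0, 0.0)))
            if h0 - h1 > _DIVERGENCE_THRESHOLD:
                divergences += 1
        else:
            accept = 0.0
            divergences += 1
        if rng.uniform() < accept:
            theta, lp, grad = th, lp_new, g
            if it >= settings.warmup:
                n_accept += 1
        elif it >= settings.warmup:
            pass
        if it >= settings.warmup:
            draws[it - settings.warmup] = theta
    rate = n_accept / settings.samples
    warning = None
    if divergences > 0.5 * total:
        warning = f"divergence rate {divergences}/{total} exceeds 50%"
    return ChainSamples(draws, rate, settings.warmup, divergences, warning, eps)


def _build_tree(logjoint, theta, p, grad, logu, direction, depth, eps, inv_mass,
                h0, rng, stats):
    if depth == 0:
        th1, p1, lp1, g1 = _leapfrog(logjoint, theta, p, grad, direction * eps,
                                     inv_mass)
        h1 = (lp1 - _kinetic(p1, inv_mass)) if np.isfinite(lp1) else -np.inf
        n1 = 1 if logu <= h1 else 0
        divergent = logu - 1000.0 > h1 if np.isfinite(h1) else True
        if divergent:
            stats["divergences"] += 1
        stats["sum_accept"] += min(1.0, np.exp(min(h1 - h0, 0.0)))
        stats["n_accept"] += 1
        return th1, p1, g1, th1, p1, g1, th1, n1, not divergent
    (tm, pm, gm, tp, pp, gp, tprop, n1, ok) = _build_tree(
        logjoint, theta, p, grad, logu, direction, depth - 1, eps, inv_mass, h0,
        rng, stats)
    if ok:
        if direction == -1:
            (tm, pm, gm, _, _, _, tprop2, n2, ok2) = _build_tree(
                logjoint, tm, pm, gm, logu, direction, depth - 1, eps, inv_mass,
                h0, rng, stats)
        else:
            (_, _, _, tp, pp, gp, tprop2, n2, ok2) = _build_tree(
                logjoint, tp, pp, gp, logu, direction, depth - 1, eps, inv_mass,
                h0, rng, stats)
        if n1 + n2 > 0 and rng.uniform() < n2 / (n1 + n2):
            tprop = tprop2
        dt = tp - tm
        ok = ok2 and (dt @ (inv_mass * pm) >= 0) and (dt @ (inv_mass * pp) >= 0)
        n1 += n2
    return tm, pm, gm, tp, pp, gp, tprop, n1, ok


def sample_nuts(
    logjoint,
    init: np.ndarray,
    settings: HMCSettings = HMCSettings(),
    seed: int = 0,
) -> ChainSamples:
    """The No-U-Turn Sampler: HMC with self-selected trajectory lengths,
    dual-averaging step-size adaptation and diagonal mass-matrix estimation
    during warmup."""
    rng = np.random.default_rng(seed)
    theta = np.asarray(init, dtype=float).copy()
    lp, grad = _check_logjoint(logjoint, theta)
    dim = theta.size
    inv_mass = (np.ones(dim) if settings.inv_mass is None
                else np.asarray(settings.inv_mass, dtype=float))
    eps = _find_reasonable_eps(logjoint, theta, rng, inv_mass)
    da = _DualAveraging(eps, settings.target_accept)
    total = settings.warmup + settings.samples
    mass_window_start = settings.warmup // 4
    mass_update_at = ((3 * settings.warmup) // 4
                      if settings.warmup >= 40 and settings.inv_mass is None
                      else None)
    window: list[np.ndarray] = []
    draws = np.empty((settings.samples, dim))
    divergences = 0
    accept_sum = 0.0
    for it in range(total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(p0, inv_mass)
        logu = h0 + np.log(rng.uniform())
        tm = tp = theta
        pm = pp = p0
        gm = gp = grad
        tprop = theta
        n = 1
        stats = {"divergences": 0, "sum_accept": 0.0, "n_accept": 0}
        for depth in range(settings.max_tree_depth):
            direction = -1 if rng.uniform() < 0.5 else 1
            if direction == -1:
                tm, pm, gm, _, _, _, tprop2, n2, ok = _build_tree(
                    logjoint, tm, pm, gm, logu, direction, depth, eps, inv_mass,
                    h0, rng, stats)
            else:
                _, _, _, tp, pp, gp, tprop2, n2, ok = _build_tree(
                    logjoint, tp, pp, gp, logu, direction, depth, eps, inv_mass,
                    h0, rng, stats)
            if ok and n + n2 > 0 and rng.uniform() < min(1.0, n2 / n):
                tprop = tprop2
            n += n2
            dt = tp - tm
            if not ok or (dt @ (inv_mass * pm)) < 0 or (dt @ (inv_mass * pp)) < 0:
                break
        if not np.array_equal(tprop, theta):
            theta = tprop
            lp, grad = logjoint(theta)
        divergences += stats["divergences"]
        accept_prob = stats["sum_accept"] / max(stats["n_accept"], 1)
        if it < settings.warmup:
            eps = da.update(accept_prob)
            if mass_update_at is not None and mass_window_start <= it < mass_update_at:
                window.append(theta.copy())
            if mass_update_at is not None and it == mass_update_at:
                W = np.array(window)
                var = W.var(axis=0)
                if np.all(var > 0):
                    inv_mass = var
                # step size must re-adapt under the new metric
                eps = _find_reasonable_eps(logjoint, theta, rng, inv_mass)
                da = _DualAveraging(eps, settings.target_accept)
            if it == settings.warmup - 1:
                eps = da.adapted
        else:
            accept_sum += accept_prob
            draws[it - settings.warmup] = theta
    warning = None
    if divergences > 0.5 * total:
        warning = f"divergence rate {divergences}/{total} exceeds 50%"
    return ChainSamples(draws, accept_sum / settings.samples, settings.warmup,
                        divergences, warning, eps)


# ---------------------------------------------------------------------------
# Geweke diagnostic


@dataclass
class GewekeResult:
    T: np.ndarray
    mean1: np.ndarray
    mean2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    n1: int
    n2: int
    critical: float
    passed: np.ndarray = field(init=False)

    def __post_init__(self):
        self.passed = np.abs(self.T) <= self.critical

    def to_json_dict(self, labels=None) -> dict:
        labels = labels or [f"p{i}" for i in range(self.T.size)]
        return {
            "critical": self.critical,
            "n1": self.n1,
            "n2": self.n2,
            "statistics": {l: float(t) for l, t in zip(labels, self.T)},
            "passed": {l: bool(p) for l, p in zip(labels, self.passed)},
        }


def geweke(
    chain,
    burn_in: float = 0.0,
    first: float = 0.10,
    last: float = 0.50,
    critical: float = 1.964,
) -> GewekeResult:
    """Per-parameter Geweke T on a chain (ChainSamples or (n, p) array).

    The burn-in fraction is discarded first (default 0: warmup is already
    gone from post-warmup chains); segment 1 is the first ``first`` fraction
    and segment 2 the last ``last`` fraction of what remains.
    """
    draws = chain.draws if isinstance(chain, ChainSamples) else np.atleast_2d(
        np.asarray(chain, dtype=float))
    if draws.ndim == 1:
        draws = draws[:, None]
    n = draws.shape[0]
    start = int(np.floor(burn_in * n))
    body = draws[start:]
    n1 = int(np.floor(first * body.shape[0]))
    n2 = int(np.floor(last * body.shape[0]))
    if n1 < 2 or n2 < 2:
        raise ValueError("chain too short: both segments need >= 2 draws")
    s1 = body[:n1]
    s2 = body[-n2:]
    v1 = s1.var(axis=0, ddof=1)
    v2 = s2.var(axis=0, ddof=1)
    if np.any(v1 == 0) or np.any(v2 == 0):
        bad = int(np.where((v1 == 0) | (v2 == 0))[0][0])
        raise DegenerateChainError(
            f"zero variance in a Geweke segment for parameter {bad}"
        )
    T = (s1.mean(axis=0) - s2.mean(axis=0)) / np.sqrt(v1 / n1 + v2 / n2)
    return GewekeResult(T, s1.mean(axis=0), s2.mean(axis=0), v1, v2, n1, n2,
                        critical)


def geweke_coefficients(chain: ChainSamples, config, **kwargs):
    """Geweke computed on the expanded polynomial coefficients: each draw is
    symbolically expanded and one chain per coefficient is tested.  Returns
    (GewekeResult, labels)."""
    from .coeff_posterior import sample_coefficients

    cs = sample_coefficients(chain, config, n_samples=chain.draws.shape[0])
    flat = cs.samples.reshape(cs.n_samples, -1)
    nout = cs.samples.shape[1]
    labels = [
        f"{o}:{lab}" if nout > 1 else lab
        for o in range(nout)
        for lab in cs.labels
    ]
    return geweke(flat, **kwargs), labels
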