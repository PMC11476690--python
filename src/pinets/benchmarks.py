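"""Synthetic benchmark systems and calibration experiments.

Four study systems, each with its data-generation settings:

* ``cubic`` — univariate cubic regression f(x) = 1 + x + 2x² + 4x³ on 200
  uniformly spaced x in [−1.25, 1.25], additive N(0, 9) noise.
* ``lotka_volterra`` — dx/dt = 1.5x − xy, dy/dt = −3y + xy from (1, 1), 100
  points on [0, 10], 10 replicate trajectories with N(0, 4) noise (sd 2).
* ``damped`` — dx/dt = −0.1x³ − 2y³, dy/dt = 2x³ − 0.1y³ from (1, 1), 500
  points on [0, 25], 10 replicates, noise sd 0.6.
* ``lorenz`` — the σ=10, r=28, b=8/3 Lorenz attractor from (1, 1, 1), 900
  points on [0, 30], 10 replicates, noise sd 2.
* ``lv_missing_terms`` — identical data to ``lotka_volterra``; the training
  configuration withholds the prey growth term 1.5x and the predator
  interaction +xy from the known model, leaving them for the network.

Ground-truth ODE trajectories come from an adaptive high-accuracy solver;
noise is i.i.d. zero-mean Gaussian, independent per replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import beta as beta_dist

from .dynamics import KnownField, ODEField, Trajectory
from .polynet import ConfigurationError

__all__ = [
    "ExperimentSpec",
    "BLRPosterior",
    "Dataset",
    "experiment_spec",
    "true_field",
    "true_regression",
    "known_and_missing_fields",
    "generate_dataset",
    "snr_profile",
    "blr_posterior",
    "cubic_design",
    "coverage_experiment",
]

SYSTEMS = ("cubic", "lotka_volterra", "damped", "lorenz", "lv_missing_terms")


@dataclass
class ExperimentSpec:
    """A benchmark system together with its generation and fit settings."""

    system: str
    params: dict = field(default_factory=dict)
    y0: tuple = ()
    t_span: tuple[float, float] = (0.0, 0.0)
    n_points: int = 0
    x_range: tuple[float, float] | None = None  # cubic only
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0
    window_length: int | None = None
    degree: int = 0
    missing_mask: tuple[str, ...] = ()

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise ConfigurationError(f"unknown system {self.system!r}")
        if self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    @property
    def state_dim(self) -> int:
        return {"cubic": 1, "lotka_volterra": 2, "damped": 2, "lorenz": 3,
                "lv_missing_terms": 2}[self.system]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("y0", "t_span", "missing_mask"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("x_range") is not None:
            d["x_range"] = tuple(d["x_range"])
        return cls(**d)


_DEFAULTS = {
    "cubic": dict(
        params={"b0": 1.0, "b1": 1.0, "b2": 2.0, "b3": 4.0},
        x_range=(-1.25, 1.25), n_points=200, noise_sd=3.0, replicates=1,
        degree=3,
    ),
    "lotka_volterra": dict(
        params={"growth": 1.5, "decay": 3.0, "interaction": 1.0},
        y0=(1.0, 1.0), t_span=(0.0, 10.0), n_points=100, noise_sd=2.0,
        replicates=10, window_length=12, degree=2,
    ),
    "damped": dict(
        params={"damping": 0.1, "coupling": 2.0},
        y0=(1.0, 1.0), t_span=(0.0, 25.0), n_points=500, noise_sd=0.6,
        replicates=10, window_length=13, degree=3,
    ),
    "lorenz": dict(
        params={"sigma": 10.0, "r": 28.0, "b": 8.0 / 3.0},
        y0=(1.0, 1.0, 1.0), t_span=(0.0, 30.0), n_points=900, noise_sd=2.0,
        replicates=10, window_length=2, degree=2,
    ),
}
_DEFAULTS["lv_missing_terms"] = dict(
    _DEFAULTS["lotka_volterra"], missing_mask=("prey_growth", "predator_interaction")
)


def experiment_spec(system: str, **overrides) -> ExperimentSpec:
    """Build the study-default :class:`ExperimentSpec` for a system, with
    optional field overrides."""
    if system not in _DEFAULTS:
        raise ConfigurationError(f"unknown system {system!r}")
    cfg = dict(_DEFAULTS[system])
    cfg.update(overrides)
    return ExperimentSpec(system=system, **cfg)


# ---------------------------------------------------------------------------
# true models


def _lv_rhs(p):
    g, dec, c = p["growth"], p["decay"], p["interaction"]

    def fn(t, y):
        x, yy = y[..., 0], y[..., 1]
        return np.stack([g * x - c * x * yy, -dec * yy + c * x * yy], axis=-1)

    return fn


def _damped_rhs(p):
    a, b = p["damping"], p["coupling"]

    def fn(t, y):
        x, yy = y[..., 0], y[..., 1]
        return np.stack([-a * x**3 - b * yy**3, b * x**3 - a * yy**3], axis=-1)

    return fn


def _lorenz_rhs(p):
    s, r, b = p["sigma"], p["r"], p["b"]

    def fn(t, y):
        x, yy, z = y[..., 0], y[..., 1], y[..., 2]
        return np.stack([s * (yy - x), x * (r - z) - yy, x * yy - b * z], axis=-1)

    return fn


def true_field(system: str, params: dict | None = None) -> ODEField:
    """The exact right-hand side of a benchmark ODE system."""
    if system == "cubic":
        raise ConfigurationError("cubic is a regression system; use true_regression")
    spec = experiment_spec(system)
    p = dict(spec.params)
    if params:
        p.update(params)
    rhs = {"lotka_volterra": _lv_rhs, "lv_missing_terms": _lv_rhs,
           "damped": _damped_rhs, "lorenz": _lorenz_rhs}[system](p)
    return KnownField(rhs, spec.state_dim)


def known_and_missing_fields(spec: ExperimentSpec):
    """For the missing-term experiment: (known field, true missing field).

    The default mask withholds the prey growth term 1.5x and the predator
    interaction +xy, so the known model is dx/dt = −xy, dy/dt = −3y.
    """
    if spec.system != "lv_missing_terms":
        raise ConfigurationError("missing-term split is defined for lv_missing_terms")
    p = spec.params
    g, dec, c = p["growth"], p["decay"], p["interaction"]
    mask = set(spec.missing_mask)

    def known(t, y):
        x, yy = y[..., 0], y[..., 1]
        dx = (0.0 if "prey_growth" in mask else g) * x - c * x * yy
        dy = -dec * yy + (0.0 if "predator_interaction" in mask else c) * x * yy
        return np.stack([np.broadcast_to(dx, x.shape), np.broadcast_to(dy, yy.shape)], axis=-1)

    def missing(t, y):
        x, yy = y[..., 0], y[..., 1]
        dx = (g if "prey_growth" in mask else 0.0) * x
        dy = (c if "predator_interaction" in mask else 0.0) * x * yy
        return np.stack([np.broadcast_to(dx, x.shape), np.broadcast_to(dy, yy.shape)], axis=-1)

    return KnownField(known, 2), KnownField(missing, 2)


def true_regression(params: dict | None = None):
    """The generating cubic f(x) = β0 + β1 x + β2 x² + β3 x³."""
    p = dict(_DEFAULTS["cubic"]["params"])
    if params:
        p.update(params)

    def fn(x):
        x = np.asarray(x, dtype=float)
        return p["b0"] + p["b1"] * x + p["b2"] * x**2 + p["b3"] * x**3

    return fn


# ---------------------------------------------------------------------------
# data generation


@dataclass
class Dataset:
    spec: ExperimentSpec
    truth: Trajectory          # noiseless; for cubic, times are the x grid
    replicates: list[Trajectory]

    @property
    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, states) with all replicates stacked."""
        t = np.concatenate([r.times for r in self.replicates])
        s = np.concatenate([r.states for r in self.replicates])
        return t, s


def generate_dataset(spec: ExperimentSpec) -> Dataset:
    """Noiseless truth plus noisy replicates, deterministic per spec.seed.

    ODE truths are integrated with an adaptive high-accuracy solver
    (DOP853 at tolerance 1e-10); the cubic truth is evaluated exactly.
    Replicates add i.i.d. N(0, noise_sd²) noise, independent per replicate.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.system == "cubic":
        x = np.linspace(*spec.x_range, spec.n_points)
        f = true_regression(spec.params)(x)
        truth = Trajectory(x, f[:, None])
    else:
        field_ = true_field(spec.system, spec.params)
        grid = np.linspace(*spec.t_span, spec.n_points)
        sol = solve_ivp(
            lambda t, y: field_(t, y),
            spec.t_span,
            np.asarray(spec.y0, dtype=float),
            t_eval=grid,
            method="DOP853",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"reference integration failed: {sol.message}")
        truth = Trajectory(grid, sol.y.T)
    replicates = [
        Trajectory(
            truth.times,
            truth.states + rng.normal(0.0, spec.noise_sd, truth.states.shape),
        )
        for _ in range(spec.replicates)
    ]
    return Dataset(spec, truth, replicates)


def snr_profile(truth: Trajectory, noise_sd: float):
    """Instantaneous signal-to-noise ratio |signal| / noise_sd per point and
    state dimension; returns (profile, (min, max))."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    prof = np.abs(truth.states) / noise_sd
    return prof, (float(prof.min()), float(prof.max()))


# ---------------------------------------------------------------------------
# Bayesian linear regression oracle


@dataclass
class BLRPosterior:
    mu: np.ndarray
    sigma: np.ndarray
    beta2: float
    alpha: float

    def interval(self, index: int, level: float) -> tuple[float, float]:
        from scipy.stats import norm

        sd = float(np.sqrt(self.sigma[index, index]))
        z = norm.ppf(0.5 + level / 2.0)
        return float(self.mu[index] - z * sd), float(self.mu[index] + z * sd)


def blr_posterior(X, y, alpha: float = 1e5, beta2: float | None = None) -> BLRPosterior:
    """Closed-form Gaussian posterior for y = XB with Gaussian noise and a
    zero-mean isotropic Gaussian prior:

        Σ_B = (XᵀX/β² + I/α²)⁻¹,   μ_B = Σ_B Xᵀy / β².

    With ``beta2=None`` the noise variance is the sample variance of the
    residuals at the ridge mode (one fixed-point pass).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if X.shape[0] == 0:
        return BLRPosterior(np.zeros(p), alpha**2 * np.eye(p), beta2 or 1.0, alpha)
    if X.shape[0] != y.size:
        raise ConfigurationError("rows(X) must equal len(y)")
    if beta2 is None:
        mode = np.linalg.solve(X.T @ X + np.eye(p) / alpha**2, X.T @ y)
        beta2 = float(np.var(y - X @ mode))
    prec = X.T @ X / beta2 + np.eye(p) / alpha**2
    sigma = np.linalg.inv(prec)
    sigma = 0.5 * (sigma + sigma.T)
    mu = sigma @ (X.T @ y) / beta2
    return BLRPosterior(mu, sigma, beta2, alpha)


def cubic_design(x: np.ndarray, degree: int = 3) -> np.ndarray:
    """Monomial design matrix [1, x, ..., x^degree]."""
    return np.vander(np.asarray(x, dtype=float).ravel(), degree + 1, increasing=True)


# ---------------------------------------------------------------------------
# coverage calibration


def _clopper_pearson(k: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    a = (1 - conf) / 2
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - a, k + 1, n - k))
    return lo, hi


def coverage_experiment(
    method: str,
    spec: ExperimentSpec,
    n_datasets: int = 100,
    seeds=None,
    levels=(0.90, 0.95),
    conf: float = 0.99,
    pipeline_kwargs: dict | None = None,
):
    """Repeat the full inference pipeline over many independently generated
    datasets and measure how often each level's credible interval contains
    the generating coefficient.

    ``method`` ∈ {"blr", "laplace", "nuts", "hmc", "vi"}.  Returns
    {level: {"fractions": per-coefficient array, "ci": per-coefficient
    Clopper–Pearson interval at ``conf``}} plus the failure count.
    """
    if spec.system != "cubic":
        raise ConfigurationError("the coverage study is defined on the cubic system")
    if method not in ("blr", "laplace", "nuts", "hmc", "vi"):
        raise ConfigurationError(f"unknown method {method!r}")
    seeds = list(seeds) if seeds is not None else list(range(1, n_datasets + 1))
    truth = np.array([spec.params["b0"], spec.params["b1"],
                      spec.params["b2"], spec.params["b3"]])
    hits = {lv: [] for lv in levels}
    failures = 0
    for sd in seeds:
        dspec = experiment_spec("cubic", seed=int(sd), noise_sd=spec.noise_sd,
                                n_points=spec.n_points, x_range=spec.x_range,
                                params=spec.params)
        ds = generate_dataset(dspec)
        x = ds.replicates[0].times
        yobs = ds.replicates[0].states[:, 0]
        try:
            if method == "blr":
                post = blr_posterior(cubic_design(x), yobs)
                for lv in levels:
                    ivs = [post.interval(i, lv) for i in range(4)]
                    hits[lv].append([lo <= truth[i] <= hi for i, (lo, hi) in enumerate(ivs)])
            else:
                from .pipeline import fit_cubic_pipeline

                cs = fit_cubic_pipeline(method, x, yobs, seed=int(sd),
                                        **(pipeline_kwargs or {}))
                from .coeff_posterior import quantile_interval

                for lv in levels:
                    row = []
                    for i, e in enumerate([(0,), (1,), (2,), (3,)]):
                        lo, hi = quantile_interval(cs.column(e), lv)
                        row.append(lo <= truth[i] <= hi)
                    hits[lv].append(row)
        except Exception:
            failures += 1
            if failures > 0.10 * len(seeds):
                raise RuntimeError(
                    f"more than 10% of coverage datasets failed ({failures})"
                )
    out = {"failures": failures, "n": len(seeds) - failures}
    for lv in levels:
        H = np.array(hits[lv], dtype=bool)
        frac = H.mean(axis=0)
        cis = [_clopper_pearson(int(H[:, i].sum()), H.shape[0], conf) for i in range(4)]
        out[lv] = {"fractions": frac, "ci": cis}
    return out
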