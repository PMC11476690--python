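"""ODE fields, differentiable fixed-step RKF45 integration, and batching.

The integrator is the 4th-order solution of the explicit Runge–Kutta–Fehlberg
pair on a fixed grid (``substeps`` equal steps per observation interval).  The
5th-order embedded estimate is never formed.  Every stage is recorded on the
forward pass so that gradients with respect to parameters and initial states
can be propagated exactly through the scheme (direct backpropagation, no
adjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polynet import (
    ConfigurationError,
    PiNetConfig,
    PiNetParams,
    pinet_forward_cached,
    pinet_vjp,
)

__all__ = [
    "ODEField",
    "KnownField",
    "PiNetField",
    "SumField",
    "Trajectory",
    "TrajectoryBatch",
    "integrate_rkf45",
    "integrate_batch",
    "integrate_batch_vjp",
    "make_batches",
    "augment_with_known",
    "IntegrationDivergenceError",
]


class IntegrationDivergenceError(RuntimeError):
    """A non-finite state was produced during integration."""


# Fehlberg 4(5) tableau; only the 4th-order weights are used, which involve
# the first five stages.
_C = np.array([0.0, 1 / 4, 3 / 8, 12 / 13, 1.0])
_A = [
    [],
    [1 / 4],
    [3 / 32, 9 / 32],
    [1932 / 2197, -7200 / 2197, 7296 / 2197],
    [439 / 216, -8.0, 3680 / 513, -845 / 4104],
]
_B4 = np.array([25 / 216, 0.0, 1408 / 2565, 2197 / 4104, -1 / 5])
_N_STAGES = 5


class ODEField:
    """Right-hand-side contract: (t, y, theta) -> dy/dt.

    ``eval`` operates on batches of states (n, state_dim); ``vjp`` propagates
    a cotangent on the output back to the states and (flat) parameters.
    Subclasses tag themselves via ``kind``.
    """

    kind = "true-model"
    state_dim: int
    n_params: int = 0

    def eval(self, t, y: np.ndarray, theta: np.ndarray | None) -> np.ndarray:
        raise NotImplementedError

    def vjp(self, t, y, theta, g, per_sample: bool = False):
        """Return (g_y, g_theta); g_theta is None for parameter-free fields,
        (n_params,) summed over the batch, or (n, n_params) per sample."""
        raise NotImplementedError

    def __call__(self, t, y, theta=None):
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            return self.eval(t, y[None, :], theta)[0]
        return self.eval(t, y, theta)


class KnownField(ODEField):
    """A fixed (parameter-free) right-hand side given as a plain function.

    ``fn(t, y)`` must accept a batch (n, state_dim) and return the same shape.
    State gradients default to central finite differences unless an analytic
    ``jac_y(t, y) -> (n, d, d)`` is supplied.
    """

    kind = "known"

    def __init__(self, fn, state_dim: int, jac_y=None, fd_eps: float = 1e-6):
        self.fn = fn
        self.state_dim = state_dim
        self.jac_y = jac_y
        self.fd_eps = fd_eps

    def eval(self, t, y, theta=None):
        return np.asarray(self.fn(t, y), dtype=float)

    def vjp(self, t, y, theta, g, per_sample=False):
        if self.jac_y is not None:
            J = self.jac_y(t, y)  # (n, d_out, d_in)
        else:
            d = self.state_dim
            cols = []
            for i in range(d):
                e = np.zeros(d)
                e[i] = self.fd_eps
                cols.append((self.fn(t, y + e) - self.fn(t, y - e)) / (2 * self.fd_eps))
            J = np.stack(cols, axis=2)
        gy = np.einsum("no,noi->ni", g, J)
        return gy, None


class ZeroField(ODEField):
    kind = "known"

    def __init__(self, state_dim: int):
        self.state_dim = state_dim

    def eval(self, t, y, theta=None):
        return np.zeros_like(y)

    def vjp(self, t, y, theta, g, per_sample=False):
        return np.zeros_like(y), None


class PiNetField(ODEField):
    """An autonomous π-net right-hand side: dy/dt = net(y; theta)."""

    kind = "pinet"

    def __init__(self, config: PiNetConfig):
        if config.output_dim != config.state_dim:
            raise ConfigurationError("an ODE field needs output_dim == state_dim")
        self.config = config
        self.state_dim = config.state_dim
        from .polynet import count_parameters

        self.n_params = count_parameters(config)

    def eval(self, t, y, theta):
        params = PiNetParams.from_vector(np.asarray(theta, dtype=float), self.config)
        out, _ = pinet_forward_cached(params, self.config, y)
        return out

    def vjp(self, t, y, theta, g, per_sample=False):
        params = PiNetParams.from_vector(np.asarray(theta, dtype=float), self.config)
        _, cache = pinet_forward_cached(params, self.config, y)
        return pinet_vjp(params, self.config, cache, g, per_sample=per_sample)


class SumField(ODEField):
    """Pointwise sum known(t, y) + learned(t, y, theta) (missing-term setup)."""

    kind = "sum"

    def __init__(self, known: ODEField, learned: ODEField):
        if known.state_dim != learned.state_dim:
            raise ConfigurationError(
                f"state_dim mismatch: known {known.state_dim} vs learned {learned.state_dim}"
            )
        self.known = known
        self.learned = learned
        self.state_dim = known.state_dim
        self.n_params = learned.n_params

    def eval(self, t, y, theta):
        return self.known.eval(t, y, None) + self.learned.eval(t, y, theta)

    def vjp(self, t, y, theta, g, per_sample=False):
        gy1, _ = self.known.vjp(t, y, None, g)
        gy2, gth = self.learned.vjp(t, y, theta, g, per_sample=per_sample)
        return gy1 + gy2, gth


def augment_with_known(known: ODEField, learned: ODEField) -> ODEField:
    """Combine a known mechanistic right-hand side with a trainable field so
    the network only has to learn the missing terms."""
    return SumField(known, learned)


# ---------------------------------------------------------------------------
# containers


@dataclass
class Trajectory:
    """A time grid and the matrix of states observed on it."""

    times: np.ndarray  # (n,)
    states: np.ndarray  # (n, state_dim)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ConfigurationError("states row count must equal grid length")
        if not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("time grid must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.states))):
            raise ConfigurationError("non-finite trajectory values")

    @property
    def state_dim(self) -> int:
        return self.states.shape[1]

    def __len__(self) -> int:
        return self.times.shape[0]


@dataclass
class TrajectoryBatch:
    """Overlapping training windows: per-window initial state, window times,
    and observed targets.

    ``weights`` (optional, per window) scale each window's squared-error
    contribution; a weight R makes one window with replicate-averaged
    targets contribute exactly what R replicate windows would (the pooled
    Gaussian objective is a function of the mean targets only).
    """

    y0: np.ndarray      # (N_t, state_dim)
    times: np.ndarray   # (N_t, L)
    targets: np.ndarray  # (N_t, L, state_dim)
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.y0 = np.atleast_2d(np.asarray(self.y0, dtype=float))
        self.times = np.atleast_2d(np.asarray(self.times, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()

    @property
    def n_windows(self) -> int:
        return self.y0.shape[0]

    @property
    def window_length(self) -> int:
        return self.times.shape[1]

    @staticmethod
    def concatenate(batches: list["TrajectoryBatch"]) -> "TrajectoryBatch":
        return TrajectoryBatch(
            np.concatenate([b.y0 for b in batches]),
            np.concatenate([b.times for b in batches]),
            np.concatenate([b.targets for b in batches]),
        )


def make_batches(
    series: Trajectory,
    L: int,
    y0_source: str = "observed",
    smoother=None,
) -> TrajectoryBatch:
    """Slice a series into all ``n - L + 1`` overlapping windows (stride 1).

    ``y0_source`` selects each window's initial state: the observed value at
    the window's first time (``"observed"``) or the prediction of a fitted
    smoother (``"smoother"``, requires ``smoother`` with a
    ``predict(times) -> (n, d)`` method).
    """
    n = len(series)
    if not 2 <= L <= n:
        raise ConfigurationError(f"window length {L} must satisfy 2 <= L <= {n}")
    if y0_source not in ("observed", "smoother"):
        raise ConfigurationError(f"unknown y0_source {y0_source!r}")
    N = n - L + 1
    idx = np.arange(L)[None, :] + np.arange(N)[:, None]
    times = series.times[idx]
    targets = series.states[idx]
    if y0_source == "observed":
        y0 = series.states[:N].copy()
    else:
        if smoother is None:
            raise ConfigurationError("y0_source='smoother' requires a fitted smoother")
        y0 = np.atleast_2d(smoother.predict(series.times[:N]))
    return TrajectoryBatch(y0, times, targets)


# ---------------------------------------------------------------------------
# integration


def _rkf45_step(field: ODEField, theta, t0, h, y, cache_stages=None):
    """One fixed step of the 4th-order Fehlberg formula for a batch of states.

    ``t0`` and ``h`` are (n, 1) arrays (per-window times/steps), ``y`` is
    (n, d).  If ``cache_stages`` is a list, the stage input states are
    appended for the reverse pass.
    """
    ks = []
    stage_inputs = []
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(_N_STAGES):
            yi = y
            for j, a in enumerate(_A[i]):
                if a != 0.0:
                    yi = yi + (h * a) * ks[j]
            stage_inputs.append(yi)
            ks.append(field.eval(t0 + _C[i] * h, yi, theta))
        y1 = y
        for i in range(_N_STAGES):
            if _B4[i] != 0.0:
                y1 = y1 + (h * _B4[i]) * ks[i]
    if cache_stages is not None:
        cache_stages.append((t0, h, stage_inputs))
    return y1


def _rkf45_step_vjp(field: ODEField, theta, step_cache, gy1, gtheta, per_sample):
    """Reverse of one step: accumulates into gtheta, returns gy0."""
    t0, h, stage_inputs = step_cache
    gk = [None] * _N_STAGES
    gy0 = gy1.copy()
    for i in range(_N_STAGES):
        if _B4[i] != 0.0:
            gk[i] = h * _B4[i] * gy1
        else:
            gk[i] = np.zeros_like(gy1)
    for i in range(_N_STAGES - 1, -1, -1):
        if not np.any(gk[i]):
            continue
        gyi, gth = field.vjp(t0 + _C[i] * h, stage_inputs[i], theta, gk[i],
                             per_sample=per_sample)
        if gth is not None:
            gtheta += gth
        gy0 += gyi
        for j, a in enumerate(_A[i]):
            if a != 0.0:
                gk[j] = gk[j] + (h * a) * gyi
    return gy0


def integrate_batch(
    field: ODEField,
    theta,
    y0: np.ndarray,
    times: np.ndarray,
    substeps: int = 10,
    want_cache: bool = False,
):
    """Integrate a batch of initial-value problems on per-window grids.

    ``y0`` is (N, d), ``times`` is (N, L); each inter-observation interval is
    covered with ``substeps`` equal steps.  Returns states (N, L, d) and,
    when ``want_cache``, the stage record needed by :func:`integrate_batch_vjp`.
    """
    if substeps < 1:
        raise ConfigurationError("substeps must be >= 1")
    y0 = np.atleast_2d(np.asarray(y0, dtype=float))
    times = np.atleast_2d(np.asarray(times, dtype=float))
    if np.any(np.diff(times, axis=1) <= 0):
        raise ConfigurationError("window times must be strictly increasing")
    N, L = times.shape
    states = np.empty((N, L, y0.shape[1]))
    states[:, 0] = y0
    cache = [] if want_cache else None
    y = y0
    for k in range(L - 1):
        h = ((times[:, k + 1] - times[:, k]) / substeps)[:, None]
        t = times[:, k][:, None].copy()
        for _ in range(substeps):
            y = _rkf45_step(field, theta, t, h, y, cache_stages=cache)
            t = t + h
        if not np.all(np.isfinite(y)):
            bad = np.where(~np.all(np.isfinite(y), axis=1))[0][0]
            raise IntegrationDivergenceError(
                f"non-finite state while integrating towards t={times[bad, k + 1]:g} "
                f"(window {bad})"
            )
        states[:, k + 1] = y
    return (states, cache) if want_cache else states


def integrate_batch_vjp(
    field: ODEField,
    theta,
    cache,
    g_states: np.ndarray,
    substeps: int,
    per_sample: bool = False,
):
    """Backpropagate cotangents on the trajectory states through the scheme.

    ``g_states`` is (N, L, d) aligned with the output of
    :func:`integrate_batch`.  Returns ``(g_y0, g_theta)``; ``g_theta`` is
    summed over windows, or (N, n_params) with ``per_sample=True``.
    """
    N, L, d = g_states.shape
    if per_sample:
        gtheta = np.zeros((N, field.n_params))
    else:
        gtheta = np.zeros(field.n_params)
    gy = g_states[:, L - 1].copy()
    step = len(cache)
    for k in range(L - 2, -1, -1):
        for _ in range(substeps):
            step -= 1
            gy = _rkf45_step_vjp(field, theta, cache[step], gy, gtheta, per_sample)
        gy += g_states[:, k]
    assert step == 0
    return gy, gtheta


def integrate_rkf45(
    field: ODEField,
    theta,
    y0: np.ndarray,
    grid: np.ndarray,
    substeps: int = 10,
) -> Trajectory:
    """Integrate a single initial-value problem over ``grid`` and return the
    trajectory sampled at the grid points."""
    y0 = np.asarray(y0, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float).ravel()
    states = integrate_batch(field, theta, y0[None, :], grid[None, :], substeps)
    return Trajectory(grid, states[0])
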