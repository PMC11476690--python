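"""ODE fields, fixed-step RKF45 integration, gradients, and batching."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pinets.dynamics import (
    IntegrationDivergenceError,
    KnownField,
    PiNetField,
    Trajectory,
    ZeroField,
    augment_with_known,
    integrate_batch,
    integrate_batch_vjp,
    integrate_rkf45,
    make_batches,
)
from pinets.polynet import ConfigurationError, PiNetConfig, count_parameters


def lv_rhs(t, y):
    x, yy = y[..., 0], y[..., 1]
    return np.stack([1.5 * x - x * yy, -3 * yy + x * yy], axis=-1)


# ---------------------------------------------------------------------------
# integration accuracy


def test_zero_field_constant_trajectory():
    tr = integrate_rkf45(ZeroField(2), None, [1.0, -2.0], np.linspace(0, 5, 11))
    assert np.all(tr.states == np.array([1.0, -2.0]))


def test_exponential_decay_closed_form():
    f = KnownField(lambda t, y: -y, 1)
    tr = integrate_rkf45(f, None, [1.0], np.linspace(0, 1, 11), substeps=1)
    assert abs(tr.states[-1, 0] - np.exp(-1)) <= 1e-6


def test_lotka_volterra_matches_adaptive_reference():
    grid = np.linspace(0, 10, 101)
    tr = integrate_rkf45(KnownField(lv_rhs, 2), None, [1.0, 1.0], grid, substeps=10)
    ref = solve_ivp(lambda t, y: lv_rhs(t, np.asarray(y)), (0, 10), [1, 1],
                    t_eval=grid, rtol=1e-10, atol=1e-12)
    assert np.max(np.abs(tr.states - ref.y.T)) <= 1e-4


def test_fourth_order_convergence():
    """Halving the substep size shrinks the error ~16x (4th-order scheme)."""
    f = KnownField(lambda t, y: -y, 1)
    errs = []
    for s in (2, 4):
        tr = integrate_rkf45(f, None, [1.0], np.array([0.0, 1.0]), substeps=s)
        errs.append(abs(tr.states[-1, 0] - np.exp(-1)))
    ratio = errs[0] / errs[1]
    assert 8 <= ratio <= 32


def test_divergence_error_names_time():
    f = KnownField(lambda t, y: y**3, 1)
    with pytest.raises(IntegrationDivergenceError, match="t="):
        integrate_rkf45(f, None, [5.0], np.linspace(0, 10, 21), substeps=2)


def test_decreasing_grid_rejected():
    with pytest.raises(ConfigurationError):
        integrate_rkf45(ZeroField(1), None, [0.0], np.array([0.0, 1.0, 0.5]))


# ---------------------------------------------------------------------------
# gradients through the scheme


def test_gradient_matches_finite_differences_linear_field():
    """d(loss)/d(theta) through the integrator vs central differences on a
    3-parameter linear field dy/dt = [a*y0, b*y1 + c*y0]."""

    class LinField(PiNetField.__mro__[1]):  # ODEField
        kind = "pinet"
        state_dim = 2
        n_params = 3

        def eval(self, t, y, theta):
            a, b, c = theta
            return np.stack([a * y[:, 0], b * y[:, 1] + c * y[:, 0]], axis=1)

        def vjp(self, t, y, theta, g, per_sample=False):
            a, b, c = theta
            gy = np.stack([a * g[:, 0] + c * g[:, 1], b * g[:, 1]], axis=1)
            if per_sample:
                gth = np.stack([g[:, 0] * y[:, 0], g[:, 1] * y[:, 1],
                                g[:, 1] * y[:, 0]], axis=1)
            else:
                gth = np.array([
                    np.sum(g[:, 0] * y[:, 0]),
                    np.sum(g[:, 1] * y[:, 1]),
                    np.sum(g[:, 1] * y[:, 0]),
                ])
            return gy, gth

    field = LinField()
    theta = np.array([-0.3, 0.2, 0.5])
    y0 = np.array([[1.0, 0.5]])
    times = np.array([[0.0, 0.4, 0.8]])
    target = np.array([[[0.9, 0.4], [0.7, 0.6], [0.5, 0.9]]])

    def loss(th):
        st = integrate_batch(field, th, y0, times, substeps=4)
        return 0.5 * np.sum((st - target) ** 2)

    st, cache = integrate_batch(field, theta, y0, times, substeps=4, want_cache=True)
    _, grad = integrate_batch_vjp(field, theta, cache, st - target, substeps=4)
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1e-6
        fd = (loss(theta + e) - loss(theta - e)) / 2e-6
        assert grad[i] == pytest.approx(fd, rel=1e-4)


def test_gradient_matches_finite_differences_pinet_field():
    cfg = PiNetConfig(2, 2, 2, hidden_widths=(4, 4, 4))
    field = PiNetField(cfg)
    rng = np.random.default_rng(3)
    theta = rng.normal(scale=0.3, size=count_parameters(cfg))
    y0 = rng.normal(size=(3, 2))
    times = np.tile(np.linspace(0, 0.6, 4), (3, 1))
    target = rng.normal(size=(3, 4, 2))

    def loss(th):
        return 0.5 * np.sum((integrate_batch(field, th, y0, times, substeps=3) - target) ** 2)

    st, cache = integrate_batch(field, theta, y0, times, substeps=3, want_cache=True)
    _, grad = integrate_batch_vjp(field, theta, cache, st - target, substeps=3)
    for i in rng.choice(theta.size, 8, replace=False):
        e = np.zeros_like(theta)
        e[i] = 1e-6
        fd = (loss(theta + e) - loss(theta - e)) / 2e-6
        assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


# ---------------------------------------------------------------------------
# batching


def test_window_count_study_setting():
    """100 points with window length 12 give 89 overlapping windows."""
    tr = Trajectory(np.linspace(0, 10, 100), np.zeros((100, 2)))
    assert make_batches(tr, 12).n_windows == 89


@pytest.mark.parametrize("n,L", [(900, 2), (50, 13), (10, 10)])
def test_window_count_formula(n, L):
    tr = Trajectory(np.linspace(0, 1, n), np.zeros((n, 1)))
    b = make_batches(tr, L)
    assert b.n_windows == n - L + 1
    assert b.window_length == L


def test_single_window_spans_series():
    tr = Trajectory(np.linspace(0, 1, 7), np.arange(7.0)[:, None])
    b = make_batches(tr, 7)
    assert b.n_windows == 1
    np.testing.assert_array_equal(b.times[0], tr.times)
    np.testing.assert_array_equal(b.targets[0], tr.states)


def test_window_length_validation():
    tr = Trajectory(np.linspace(0, 1, 5), np.zeros((5, 1)))
    for L in (1, 6):
        with pytest.raises(ConfigurationError):
            make_batches(tr, L)


def test_batching_conserves_data():
    """Every (time, observation) pair of the source series appears in at
    least one window."""
    rng = np.random.default_rng(0)
    tr = Trajectory(np.linspace(0, 1, 30), rng.normal(size=(30, 2)))
    b = make_batches(tr, 5)
    covered = set()
    for w in range(b.n_windows):
        for l in range(b.window_length):
            covered.add((b.times[w, l], tuple(b.targets[w, l])))
    source = {(t, tuple(s)) for t, s in zip(tr.times, tr.states)}
    assert source <= covered


def test_windows_are_consecutive_subsequences():
    tr = Trajectory(np.linspace(0, 2, 20), np.zeros((20, 1)))
    b = make_batches(tr, 4)
    for w in range(b.n_windows):
        np.testing.assert_array_equal(b.times[w], tr.times[w : w + 4])


def test_smoother_initial_conditions():
    class FakeSmoother:
        def predict(self, times):
            return np.stack([times, 2 * times], axis=1)

    tr = Trajectory(np.linspace(0, 1, 10), np.ones((10, 2)))
    b = make_batches(tr, 3, y0_source="smoother", smoother=FakeSmoother())
    np.testing.assert_allclose(b.y0[:, 1], 2 * tr.times[:8])


# ---------------------------------------------------------------------------
# known + learned fields


def test_augment_identities():
    zero = ZeroField(2)
    lv = KnownField(lv_rhs, 2)
    pts = np.random.default_rng(1).normal(size=(100, 2))
    np.testing.assert_array_equal(augment_with_known(lv, zero).eval(0, pts, None),
                                  lv.eval(0, pts, None))
    np.testing.assert_array_equal(augment_with_known(zero, lv).eval(0, pts, None),
                                  lv.eval(0, pts, None))


def test_augment_pointwise_sum_oracle():
    f1 = KnownField(lambda t, y: np.sin(y), 2)
    f2 = KnownField(lambda t, y: y**2, 2)
    s = augment_with_known(f1, f2)
    pts = np.random.default_rng(2).normal(size=(100, 2))
    np.testing.assert_allclose(s.eval(0.0, pts, None), np.sin(pts) + pts**2)


def test_augment_dimension_mismatch():
    with pytest.raises(ConfigurationError):
        augment_with_known(ZeroField(2), ZeroField(3))
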