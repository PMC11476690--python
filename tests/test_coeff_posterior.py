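"""Monte-Carlo propagation to coefficient posteriors, intervals, bands."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinets.coeff_posterior import (
    density_summary,
    posterior_predictive,
    quantile_interval,
    sample_coefficients,
)
from pinets.laplace import GaussianPosterior
from pinets.polynet import (
    ConfigurationError,
    PiNetConfig,
    PiNetParams,
    count_parameters,
    expand_to_polynomial,
)

TINY = PiNetConfig(1, 1, 1, hidden_widths=(1, 1))  # 5 params: A(w,b), P(w,b), Wo


def tiny_theta(a_w=1.0, a_b=0.0, p_w=1.0, p_b=0.0, w_o=1.0):
    return np.array([a_w, a_b, p_w, p_b, w_o])


# ---------------------------------------------------------------------------
# coefficient sampling


def test_zero_covariance_posterior_gives_identical_samples():
    cfg = PiNetConfig(1, 1, 2)
    mean = np.random.default_rng(0).normal(size=count_parameters(cfg))
    post = GaussianPosterior(mean, np.zeros((mean.size, mean.size)))
    cs = sample_coefficients(post, cfg, n_samples=50, seed=1)
    expected = expand_to_polynomial(PiNetParams.from_vector(mean, cfg), cfg).coeffs
    assert np.all(cs.samples == cs.samples[0])
    np.testing.assert_allclose(cs.samples[0], expected)


def test_identity_mapping_preserves_gaussian():
    """When only one weight is uncertain and every other parameter is the
    identity, the coefficient posterior equals the weight posterior."""
    mean = tiny_theta(a_w=3.0)
    cov = np.zeros((5, 5))
    cov[0, 0] = 0.25  # var of the input weight only
    cs = sample_coefficients(GaussianPosterior(mean, cov), TINY, 40_000, seed=2)
    col = cs.column((1,))
    assert col.mean() == pytest.approx(3.0, abs=0.02)
    assert col.var() == pytest.approx(0.25, rel=0.05)


def test_product_of_independent_gaussians_moments():
    """coefficient(x) = w1·w2 for independent Gaussian w1, w2: mean μ1μ2 and
    variance μ1²σ2² + μ2²σ1² + σ1²σ2² (Gaussian product-moment formula)."""
    mu1, s1 = 2.0, 0.3
    mu2, s2 = -1.5, 0.4
    mean = tiny_theta(a_w=mu1, w_o=mu2)
    cov = np.zeros((5, 5))
    cov[0, 0] = s1**2
    cov[4, 4] = s2**2
    cs = sample_coefficients(GaussianPosterior(mean, cov), TINY, 200_000, seed=3)
    col = cs.column((1,))
    assert col.mean() == pytest.approx(mu1 * mu2, abs=0.01)
    want_var = mu1**2 * s2**2 + mu2**2 * s1**2 + s1**2 * s2**2
    assert col.var() == pytest.approx(want_var, rel=0.02)


def test_chain_samples_are_reused():
    from pinets.mcmc import ChainSamples

    rng = np.random.default_rng(4)
    draws = rng.normal(size=(300, 5))
    chain = ChainSamples(draws, 0.9, 0)
    cs = sample_coefficients(chain, TINY, n_samples=1000, seed=5)
    assert cs.n_samples == 300  # capped at chain length
    # last draw expands to the last coefficient sample
    want = expand_to_polynomial(PiNetParams.from_vector(draws[-1], TINY), TINY).coeffs
    np.testing.assert_allclose(cs.samples[-1], want)


def test_layout_mismatch_raises():
    post = GaussianPosterior(np.zeros(7), np.eye(7))
    with pytest.raises(ConfigurationError):
        sample_coefficients(post, TINY, 10, 0)


# ---------------------------------------------------------------------------
# quantile intervals


def test_quantile_interval_limits_and_degenerate():
    s = np.array([3.0, -1.0, 5.0, 2.0])
    lo, hi = quantile_interval(s, 0.999999)
    assert (lo, hi) == pytest.approx((-1.0, 5.0), abs=1e-3)
    lo, hi = quantile_interval(np.full(10, 2.5), 0.9)
    assert lo == hi == 2.5


def test_quantile_interval_normal_endpoints():
    draws = np.random.default_rng(6).standard_normal(1_000_000)
    lo, hi = quantile_interval(draws, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.02)
    assert hi == pytest.approx(1.96, abs=0.02)


def test_quantile_interval_domain():
    with pytest.raises(ValueError):
        quantile_interval(np.ones(5), 1.5)
    with pytest.raises(ValueError):
        quantile_interval(np.array([1.0]), 0.9)


@given(st.floats(0.05, 0.9), st.floats(0.91, 0.999))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_quantile_intervals_nest(narrow, wide):
    s = np.random.default_rng(7).standard_normal(5000)
    lo_n, hi_n = quantile_interval(s, narrow)
    lo_w, hi_w = quantile_interval(s, wide)
    assert lo_w <= lo_n and hi_n <= hi_w


def test_interval_coverage_calibration():
    """Empirical coverage of the quantile interval on a known Gaussian
    matches the nominal level within binomial error at n=10000."""
    rng = np.random.default_rng(8)
    level = 0.9
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        s = rng.standard_normal(10_000)
        lo, hi = quantile_interval(s + 1.7, level)  # N(1.7, 1) samples
        hits += lo <= 1.7 <= hi
    # the interval contains the true MEAN essentially always at this n;
    # instead check tail mass: fraction of draws inside ≈ level
    s = rng.standard_normal(10_000) * 2.0
    lo, hi = quantile_interval(s, level)
    inside = np.mean((s >= lo) & (s <= hi))
    assert inside == pytest.approx(level, abs=3 * np.sqrt(level * (1 - level) / 10_000) + 2e-4)


# ---------------------------------------------------------------------------
# posterior predictive


def test_degenerate_posterior_zero_width_band():
    cfg = PiNetConfig(2, 2, 2)
    theta = np.random.default_rng(9).normal(scale=0.2, size=count_parameters(cfg))
    post = GaussianPosterior(theta, np.zeros((theta.size,) * 2))
    grid = np.linspace(0, 1.0, 6)
    band = posterior_predictive(post, cfg, y0=[0.5, 0.5], grid=grid,
                                levels=(0.95,), n_samples=30, seed=0)
    from pinets.dynamics import PiNetField, integrate_rkf45

    truth = integrate_rkf45(PiNetField(cfg), theta, [0.5, 0.5], grid)
    np.testing.assert_allclose(band.mean, truth.states, rtol=1e-7, atol=1e-9)
    np.testing.assert_allclose(band.lower[0.95], band.upper[0.95], atol=1e-9)


def test_band_nesting_and_mean_between():
    cfg = PiNetConfig(1, 1, 2)
    rng = np.random.default_rng(10)
    theta = rng.normal(scale=0.4, size=count_parameters(cfg))
    post = GaussianPosterior(theta, 0.01 * np.eye(theta.size))
    band = posterior_predictive(post, cfg, x_grid=np.linspace(-1, 1, 20),
                                levels=(0.95, 0.997), n_samples=500, seed=1)
    assert np.all(band.lower[0.997] <= band.lower[0.95])
    assert np.all(band.upper[0.95] <= band.upper[0.997])
    assert np.all(band.lower[0.95] <= band.mean) and np.all(band.mean <= band.upper[0.95])


def test_cubic_band_covers_true_function(cubic_dataset):
    """The 95% predictive band of the Laplace fit covers the generating
    cubic pointwise at >= 85% of fresh grid locations."""
    from pinets.pipeline import fit_cubic_pipeline
    from pinets.benchmarks import true_regression

    _, x, y = cubic_dataset
    res = fit_cubic_pipeline("laplace", x, y, seed=989, epochs=2500,
                             full_result=True, n_coeff_samples=500)
    fresh = np.linspace(-1.2, 1.2, 60)
    band = posterior_predictive(res.posterior, res.config, x_grid=fresh,
                                levels=(0.95,), n_samples=800, seed=2)
    f = true_regression()(fresh)
    covered = np.mean((band.lower[0.95][:, 0] <= f) & (f <= band.upper[0.95][:, 0]))
    assert covered >= 0.85


def test_divergent_draws_are_excluded_or_error():
    cfg = PiNetConfig(1, 1, 2)
    # an explosive quadratic field: dy/dt = y^2 from y0=1 blows past t=1
    theta = np.zeros(count_parameters(cfg))
    post = GaussianPosterior(theta, 4.0 * np.eye(theta.size))
    with pytest.raises(RuntimeError):
        posterior_predictive(post, cfg, y0=[2.0], grid=np.linspace(0, 5, 20),
                             levels=(0.9,), n_samples=100, seed=3, substeps=2)


# ---------------------------------------------------------------------------
# density summaries


def test_density_peak_and_normalization():
    s = np.random.default_rng(11).standard_normal(20_000)
    d = density_summary(s)
    peak = d.grid[np.argmax(d.density)]
    assert abs(peak) <= 0.15
    integral = np.trapezoid(d.density, d.grid)
    assert integral == pytest.approx(1.0, abs=0.01)


def test_density_shifted_mode():
    s = np.random.default_rng(12).standard_normal(20_000) + 7.0
    d = density_summary(s)
    assert abs(d.grid[np.argmax(d.density)] - 7.0) <= 0.15


def test_density_point_mass_flag():
    d = density_summary(np.full(100, 3.25))
    assert d.density is None
    assert d.point_mass == 3.25
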