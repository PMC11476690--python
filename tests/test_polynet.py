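"""π-net architecture: forward evaluation, exact expansion, initialization."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from pinets.polynet import (
    ConfigurationError,
    PiNetConfig,
    PiNetParams,
    count_parameters,
    expand_to_polynomial,
    init_params,
    monomial_exponents,
    pinet_forward,
)

CONFIGS = [
    PiNetConfig(1, 1, 1),
    PiNetConfig(1, 1, 3),
    PiNetConfig(2, 2, 2),
    PiNetConfig(2, 1, 3, hidden_widths=(4, 4, 4, 4)),
    PiNetConfig(3, 3, 2, hidden_widths=(6, 6, 6)),
]


def random_params(config, seed):
    rng = np.random.default_rng(seed)
    return PiNetParams.from_vector(
        rng.normal(size=count_parameters(config)), config
    )


# ---------------------------------------------------------------------------
# forward / expansion


@pytest.mark.parametrize("config", CONFIGS, ids=str)
def test_forward_equals_expansion(config):
    """The network forward pass and its symbolic expansion are the same
    polynomial, on batches of random inputs."""
    for seed in range(5):
        params = random_params(config, seed)
        x = np.random.default_rng(100 + seed).normal(size=(20, config.state_dim))
        y_net = pinet_forward(params, config, x)
        y_poly = expand_to_polynomial(params, config)(x)
        np.testing.assert_allclose(y_net, y_poly, rtol=1e-9, atol=1e-9)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_forward_expansion_property(seed):
    config = PiNetConfig(2, 2, 2, hidden_widths=(5, 5, 5))
    params = random_params(config, seed)
    x = np.random.default_rng(seed).uniform(-2, 2, size=(8, 2))
    err = np.abs(pinet_forward(params, config, x) - expand_to_polynomial(params, config)(x))
    assert np.all(err <= 1e-9 * (1 + np.abs(pinet_forward(params, config, x))))


def test_zero_params_zero_output():
    config = PiNetConfig(2, 2, 2)
    params = PiNetParams.from_vector(np.zeros(count_parameters(config)), config)
    x = np.random.default_rng(0).normal(size=(7, 2))
    assert np.all(pinet_forward(params, config, x) == 0.0)
    assert np.all(expand_to_polynomial(params, config).coeffs == 0.0)


def test_scalar_input_is_cubic_polynomial():
    """A 1-D input traced through the degree-3 wiring is exactly a cubic:
    four monomials reproduce the network everywhere."""
    config = PiNetConfig(1, 1, 3)
    params = random_params(config, 7)
    form = expand_to_polynomial(params, config)
    assert sorted(form.exponents) == [(0,), (1,), (2,), (3,)]
    xs = np.linspace(-3, 3, 41)[:, None]
    np.testing.assert_allclose(
        pinet_forward(params, config, xs), form(xs), rtol=1e-9, atol=1e-12
    )


def test_expansion_against_sympy():
    """Independent symbolic route: build the same wiring in sympy, expand,
    and compare every coefficient."""
    config = PiNetConfig(2, 1, 2, hidden_widths=(3, 3, 3))
    params = random_params(config, 11)
    x, y = sp.symbols("x y")
    vec = sp.Matrix([[x, y]])
    zs = None
    k = config.degree
    for j in range(k):
        u = vec * sp.Matrix(params.weights[j]) + sp.Matrix([params.biases[j]])
        if zs is None:
            zs = u
        else:
            zs = zs + sp.Matrix([[u[0, i] * zs[0, i] for i in range(u.shape[1])]])
    v = zs * sp.Matrix(params.weights[k]) + sp.Matrix([params.biases[k]])
    out = sp.expand((v * sp.Matrix(params.weights[k + 1]))[0, 0])
    form = expand_to_polynomial(params, config)
    poly = sp.Poly(out, x, y)
    for e in form.exponents:
        got = form.coefficient(e)
        want = float(poly.coeff_monomial(x ** e[0] * y ** e[1]))
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


def test_expansion_against_interpolation_oracle():
    """Coefficients recovered by solving a linear system from forward
    evaluations on a grid agree with the symbolic expansion."""
    config = PiNetConfig(2, 1, 3, hidden_widths=(5, 5, 5, 5))
    params = random_params(config, 3)
    exps = monomial_exponents(2, 3)
    rng = np.random.default_rng(5)
    pts = rng.uniform(-1.5, 1.5, size=(3 * len(exps), 2))
    design = np.stack([np.prod(pts**np.array(e), axis=1) for e in exps], axis=1)
    target = pinet_forward(params, config, pts)[:, 0]
    recovered, *_ = np.linalg.lstsq(design, target, rcond=None)
    form = expand_to_polynomial(params, config)
    np.testing.assert_allclose(recovered, form.coeffs[0], rtol=1e-8, atol=1e-8)


def test_degree_bound():
    for config in CONFIGS:
        form = expand_to_polynomial(random_params(config, 1), config)
        assert all(sum(e) <= config.degree for e in form.exponents)


def test_like_terms_combined():
    form = expand_to_polynomial(random_params(PiNetConfig(2, 2, 2), 0), PiNetConfig(2, 2, 2))
    assert len(set(form.exponents)) == len(form.exponents)


# ---------------------------------------------------------------------------
# parameter counting


def test_parameter_count_study_architecture():
    """The degree-3 width-10 scalar network has 180 parameters."""
    assert count_parameters(PiNetConfig(1, 1, 3, hidden_widths=(10, 10, 10, 10))) == 180


def test_parameter_count_degree_one():
    # smallest possible net: 1->1 layers throughout
    cfg = PiNetConfig(1, 1, 1, hidden_widths=(1, 1))
    assert count_parameters(cfg) == 2 + 2 + 1


@pytest.mark.parametrize("config", CONFIGS, ids=str)
def test_parameter_count_shape_walk(config):
    """Independent shape walk: Σ (fan_in + has_bias) · fan_out over layers."""
    total = 0
    for (fan_in, fan_out), bias in config.layer_shapes():
        total += fan_in * fan_out + bias
    assert count_parameters(config) == total
    assert random_params(config, 0).to_vector().size == total


def test_params_config_mismatch_raises():
    good = random_params(PiNetConfig(2, 2, 2), 0)
    with pytest.raises(ConfigurationError):
        good.check(PiNetConfig(2, 2, 3))
    with pytest.raises(ConfigurationError):
        pinet_forward(good, PiNetConfig(2, 2, 2), np.zeros(3))


def test_unequal_hidden_widths_rejected():
    with pytest.raises(ConfigurationError):
        PiNetConfig(1, 1, 2, hidden_widths=(10, 5, 10))


# ---------------------------------------------------------------------------
# initialization


def test_init_coefficients_in_band():
    config = PiNetConfig(1, 1, 3)
    params = init_params(config, seed=4)
    mags = np.abs(expand_to_polynomial(params, config).coeffs)
    nz = mags[mags > 0]
    assert nz.max() <= 1e-5
    assert nz.min() >= 1e-10


@pytest.mark.parametrize("config", [PiNetConfig(2, 2, 2), PiNetConfig(1, 1, 3)], ids=str)
def test_init_deterministic_and_seed_sensitive(config):
    a = init_params(config, seed=1).to_vector()
    b = init_params(config, seed=1).to_vector()
    c = init_params(config, seed=2).to_vector()
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_init_rejects_bad_band():
    with pytest.raises(ConfigurationError):
        init_params(PiNetConfig(1, 1, 2), seed=0, coeff_lo=1e-5, coeff_hi=1e-10)


# ---------------------------------------------------------------------------
# serialization


def test_polynomial_form_json(tmp_path):
    import json

    config = PiNetConfig(2, 2, 2)
    form = expand_to_polynomial(random_params(config, 9), config)
    path = tmp_path / "form.json"
    form.to_json(path)
    loaded = json.loads(path.read_text())
    assert set(loaded) == {"dx/dt", "dy/dt"}
    assert loaded["dx/dt"]["x*y"] == pytest.approx(form.coefficient((1, 1), 0))
    assert loaded["dy/dt"]["1"] == pytest.approx(form.coefficient((0, 0), 1))
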