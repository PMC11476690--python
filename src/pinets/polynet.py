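"""Polynomial (π-net) architecture: forward pass, gradients, and exact expansion.

A π-net is a neural network built entirely from linear layers combined by
Hadamard (elementwise) products, with no nonlinear activations.  Its output is
therefore an exact multivariate polynomial of its input, and the network can be
algebraically expanded into explicit monomial coefficients.

Wiring used here (degree ``k``, hidden width ``h``, input dim ``d``):

    z_1 = A_1(x)                          A_j: biased linear  d -> h
    z_j = A_j(x) ∘ z_{j-1} + z_{j-1}      j = 2..k   (Hadamard + skip)
    v   = P(z_k)                          P: biased linear    h -> h
    y   = v @ W_out                       read-out h -> out, no bias

``z_j`` has total degree j in x, so the output has total degree ≤ k (the skip
connections retain every lower-order term).  For degree 3 with h = 10 and a
scalar input/output this is the 1x10x10x10x10x1 layout with exactly 180
scalar parameters.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PiNetConfig",
    "PiNetParams",
    "PolynomialForm",
    "pinet_forward",
    "pinet_forward_cached",
    "pinet_vjp",
    "expand_to_polynomial",
    "expand_batch",
    "init_params",
    "count_parameters",
    "monomial_exponents",
]


class ConfigurationError(ValueError):
    """Raised when parameters, shapes, or settings are inconsistent."""


class InitializationError(RuntimeError):
    """Raised when small-coefficient initialization cannot reach the target band."""


@dataclass(frozen=True)
class PiNetConfig:
    """Architecture of a π-net.

    Parameters
    ----------
    state_dim : input dimensionality (number of state variables).
    output_dim : number of network outputs (state_dim for an ODE field).
    degree : maximum total polynomial degree of the output.
    hidden_widths : widths of the hidden layers; ``degree + 1`` equal entries
        (``degree`` Hadamard stages plus the penultimate linear layer).  The
        Hadamard wiring requires all of them to be equal.
    """

    state_dim: int
    output_dim: int
    degree: int
    hidden_widths: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.state_dim < 1 or self.output_dim < 1 or self.degree < 1:
            raise ConfigurationError("state_dim, output_dim and degree must be >= 1")
        widths = self.hidden_widths
        if widths is None:
            widths = (10,) * (self.degree + 1)
        widths = tuple(int(w) for w in widths)
        if len(widths) != self.degree + 1:
            raise ConfigurationError(
                f"hidden_widths must have degree+1={self.degree + 1} entries, got {len(widths)}"
            )
        if any(w < 1 for w in widths):
            raise ConfigurationError("hidden widths must be positive")
        if len(set(widths)) != 1:
            raise ConfigurationError(
                "Hadamard-product wiring requires equal hidden widths"
            )
        object.__setattr__(self, "hidden_widths", widths)

    @property
    def width(self) -> int:
        return self.hidden_widths[0]

    def layer_shapes(self) -> list[tuple[tuple[int, int], int]]:
        """((fan_in, fan_out), bias_size) per linear layer, in order.

        bias_size 0 marks the bias-free read-out.
        """
        h = self.width
        shapes = [((self.state_dim, h), h) for _ in range(self.degree)]
        shapes.append(((h, h), h))
        shapes.append(((h, self.output_dim), 0))
        return shapes


@dataclass
class PiNetParams:
    """Ordered (weight, bias) pairs for every linear layer of a π-net.

    ``biases[-1]`` is an empty array: the read-out layer carries no bias.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def check(self, config: PiNetConfig) -> None:
        shapes = config.layer_shapes()
        if len(self.weights) != len(shapes) or len(self.biases) != len(shapes):
            raise ConfigurationError("wrong number of layers for config")
        for (w, b), (wshape, bsize) in zip(zip(self.weights, self.biases), shapes):
            if w.shape != wshape or b.shape != (bsize,):
                raise ConfigurationError(
                    f"layer shape mismatch: got {w.shape}/{b.shape}, want {wshape}/({bsize},)"
                )
        for arr in (*self.weights, *self.biases):
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError("non-finite parameter entries")

    # -- flat-vector conversion (documented layout: per layer, W then b, C order)
    def to_vector(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec: np.ndarray, config: PiNetConfig) -> "PiNetParams":
        weights, biases = [], []
        pos = 0
        for (wshape, bsize) in config.layer_shapes():
            n = wshape[0] * wshape[1]
            weights.append(vec[pos : pos + n].reshape(wshape))
            pos += n
            biases.append(vec[pos : pos + bsize].copy())
            pos += bsize
        if pos != vec.size:
            raise ConfigurationError(
                f"parameter vector length {vec.size} != {count_parameters(config)}"
            )
        return cls(weights, biases)

    def copy(self) -> "PiNetParams":
        return PiNetParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])


def count_parameters(config: PiNetConfig) -> int:
    """Total number of scalar weights and biases defined by ``config``."""
    return sum(i * o + b for (i, o), b in config.layer_shapes())


# ---------------------------------------------------------------------------
# forward / backward


def _split(params: PiNetParams, config: PiNetConfig):
    k = config.degree
    return (
        params.weights[:k],
        params.biases[:k],
        params.weights[k],
        params.biases[k],
        params.weights[k + 1],
    )


def pinet_forward_cached(params: PiNetParams, config: PiNetConfig, x: np.ndarray):
    """Forward pass returning (output, cache) with the intermediates needed
    for a later vector-Jacobian product.  ``x`` is (n, state_dim)."""
    Wa, ba, Wp, bp, Wo = _split(params, config)
    us = [x @ W + b for W, b in zip(Wa, ba)]
    zs = [us[0]]
    for u in us[1:]:
        zs.append(u * zs[-1] + zs[-1])
    v = zs[-1] @ Wp + bp
    y = v @ Wo
    return y, (x, us, zs, v)


def pinet_forward(params: PiNetParams, config: PiNetConfig, x: np.ndarray) -> np.ndarray:
    """Evaluate the π-net.

    ``x`` may be a single state vector (state_dim,) or a batch (n, state_dim);
    the output matches (output_dim,) or (n, output_dim).
    """
    params.check(config)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != config.state_dim:
        raise ConfigurationError(
            f"input has dimension {xb.shape[1]}, config.state_dim is {config.state_dim}"
        )
    y, _ = pinet_forward_cached(params, config, xb)
    return y[0] if single else y


def pinet_vjp(params: PiNetParams, config: PiNetConfig, cache, gy: np.ndarray,
              per_sample: bool = False):
    """Vector-Jacobian product of the forward pass.

    Given the cotangent ``gy`` (n, output_dim) of the output, returns
    ``(gx, gparams)`` where ``gx`` is (n, state_dim) and ``gparams`` is a flat
    gradient vector in the :meth:`PiNetParams.to_vector` layout (summed over
    the batch).  With ``per_sample=True`` the parameter gradient is returned
    per batch row, shape (n, n_params).
    """
    Wa, ba, Wp, bp, Wo = _split(params, config)
    x, us, zs, v = cache
    n = x.shape[0]
    k = config.degree

    if per_sample:
        def outer(a, g):  # (n,i),(n,j) -> (n, i*j)
            return (a[:, :, None] * g[:, None, :]).reshape(n, -1)
    gWo = (v.T @ gy) if not per_sample else outer(v, gy)
    gv = gy @ Wo.T
    gWp = (zs[-1].T @ gv) if not per_sample else outer(zs[-1], gv)
    gbp = gv.sum(axis=0) if not per_sample else gv

    gz = gv @ Wp.T
    gus = [None] * k
    for j in range(k - 1, 0, -1):
        gus[j] = gz * zs[j - 1]
        gz = gz * (us[j] + 1.0)
    gus[0] = gz

    gx = np.zeros_like(x)
    gWa, gba = [], []
    for j in range(k):
        gu = gus[j]
        gx += gu @ Wa[j].T
        gWa.append((x.T @ gu) if not per_sample else outer(x, gu))
        gba.append(gu.sum(axis=0) if not per_sample else gu)

    if per_sample:
        parts = []
        for j in range(k):
            parts.append(gWa[j])
            parts.append(gba[j])
        parts.append(gWp)
        parts.append(gbp)
        parts.append(gWo)
        gparams = np.concatenate(parts, axis=1)
    else:
        parts = []
        for j in range(k):
            parts.append(gWa[j].ravel())
            parts.append(gba[j].ravel())
        parts.append(gWp.ravel())
        parts.append(gbp.ravel())
        parts.append(gWo.ravel())
        gparams = np.concatenate(parts)
    return gx, gparams


# ---------------------------------------------------------------------------
# exact symbolic expansion on exponent-vector maps


def monomial_exponents(state_dim: int, degree: int) -> list[tuple[int, ...]]:
    """All exponent vectors of total degree <= degree, graded-lexicographic."""
    out = []
    for total in range(degree + 1):
        combos = [
            e
            for e in itertools.product(range(total + 1), repeat=state_dim)
            if sum(e) == total
        ]
        out.extend(sorted(combos, reverse=True))
    return out


def _shift_tables(exps: list[tuple[int, ...]], state_dim: int, degree: int):
    """For each variable i, a map monomial-index -> index of monomial * x_i
    (or -1 when the product exceeds the degree bound)."""
    index = {e: i for i, e in enumerate(exps)}
    tables = np.full((state_dim, len(exps)), -1, dtype=int)
    for i in range(state_dim):
        for m, e in enumerate(exps):
            e2 = list(e)
            e2[i] += 1
            tables[i, m] = index.get(tuple(e2), -1)
    return tables


@dataclass
class PolynomialForm:
    """Exact polynomial expansion of a π-net: one coefficient per monomial
    per output dimension.

    ``coeffs`` is (output_dim, n_monomials); column m corresponds to
    ``exponents[m]`` (an exponent tuple of length state_dim).
    """

    exponents: list[tuple[int, ...]]
    coeffs: np.ndarray
    var_names: tuple[str, ...]

    def coefficient(self, exponent: tuple[int, ...], output: int = 0) -> float:
        return float(self.coeffs[output, self.exponents.index(tuple(exponent))])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the polynomial at x (vector or (n, state_dim) batch)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        xb = x[None, :] if single else x
        powers = np.stack(
            [np.prod(xb ** np.array(e, dtype=float), axis=1) for e in self.exponents],
            axis=1,
        )
        y = powers @ self.coeffs.T
        return y[0] if single else y

    def monomial_label(self, exponent: tuple[int, ...]) -> str:
        parts = []
        for name, p in zip(self.var_names, exponent):
            if p == 1:
                parts.append(name)
            elif p > 1:
                parts.append(f"{name}^{p}")
        return "*".join(parts) if parts else "1"

    def as_dict(self) -> dict[str, dict[str, float]]:
        """JSON-ready {output_name: {monomial label: coefficient}}.

        Variable ordering is fixed by ``var_names`` (x, y, z, ... by default);
        output names are the variable names when output_dim == state_dim
        (an ODE right-hand side) and ``f0, f1, ...`` otherwise.
        """
        nout = self.coeffs.shape[0]
        if nout == len(self.var_names):
            out_names = [f"d{v}/dt" for v in self.var_names]
        else:
            out_names = [f"f{i}" for i in range(nout)]
        return {
            out_names[i]: {
                self.monomial_label(e): float(self.coeffs[i, m])
                for m, e in enumerate(self.exponents)
            }
            for i in range(nout)
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


_DEFAULT_NAMES = ("x", "y", "z", "w", "u", "v")


def _var_names(state_dim: int) -> tuple[str, ...]:
    if state_dim <= len(_DEFAULT_NAMES):
        return _DEFAULT_NAMES[:state_dim]
    return tuple(f"x{i}" for i in range(state_dim))


def expand_batch(theta: np.ndarray, config: PiNetConfig) -> np.ndarray:
    """Expand a batch of flat parameter vectors (n, n_params) into coefficient
    arrays (n, output_dim, n_monomials).  Exact polynomial arithmetic on
    exponent-vector maps; no string manipulation."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n = theta.shape[0]
    d, k, h = config.state_dim, config.degree, config.width
    exps = monomial_exponents(d, k)
    M = len(exps)
    shift = _shift_tables(exps, d, k)

    # unpack layer parameters for the whole batch
    shapes = config.layer_shapes()
    Ws, Bs, pos = [], [], 0
    for (wshape, bsize) in shapes:
        nw = wshape[0] * wshape[1]
        Ws.append(theta[:, pos : pos + nw].reshape(n, *wshape))
        pos += nw
        Bs.append(theta[:, pos : pos + bsize])
        pos += bsize
    if pos != theta.shape[1]:
        raise ConfigurationError("parameter vector length does not match config")

    def affine_coeffs(W, b):
        """Coefficient representation of A(x) = xW + b: (n, h, M)."""
        C = np.zeros((n, W.shape[2], M))
        C[:, :, 0] = b
        for i in range(d):
            # monomial index of plain x_i is shift[i, 0]
            C[:, :, shift[i, 0]] = W[:, i, :]
        return C

    Z = affine_coeffs(Ws[0], Bs[0])
    for j in range(1, k):
        Wj, bj = Ws[j], Bs[j]
        # (A_j(x) + 1) ∘ z: multiply polynomial z by affine poly, monomial shifts
        new = Z * (bj + 1.0)[:, :, None]
        for i in range(d):
            dest = shift[i]
            ok = dest >= 0
            # the map e -> e + e_i is injective, so plain fancy-index add is safe
            new[:, :, dest[ok]] += Z[:, :, ok] * Wj[:, i, :][:, :, None]
        Z = new
    # penultimate biased linear, then bias-free read-out
    V = np.einsum("nhm,nho->nom", Z, Ws[k])
    V[:, :, 0] += Bs[k]
    Y = np.einsum("nhm,nho->nom", V, Ws[k + 1])
    return Y


def expand_to_polynomial(params: PiNetParams, config: PiNetConfig) -> PolynomialForm:
    """Expand a π-net into its exact polynomial form (like terms combined)."""
    params.check(config)
    coeffs = expand_batch(params.to_vector()[None, :], config)[0]
    return PolynomialForm(
        exponents=monomial_exponents(config.state_dim, config.degree),
        coeffs=coeffs,
        var_names=_var_names(config.state_dim),
    )


# ---------------------------------------------------------------------------
# initialization


def init_params(
    config: PiNetConfig,
    seed: int,
    coeff_lo: float = 1e-10,
    coeff_hi: float = 1e-5,
    max_attempts: int = 200,
) -> PiNetParams:
    """Draw parameters whose *expanded* polynomial coefficients all start with
    magnitudes inside ``[coeff_lo, coeff_hi]``.

    Hidden-layer entries are drawn with magnitude near 1 (uniform in
    ±[0.5, 1.5]) so products across Hadamard stages neither explode nor
    vanish; every expanded coefficient is exactly linear in the read-out
    weights, so the read-out layer alone is rescaled by a common factor that
    places the coefficient magnitudes inside the band.  Draws whose
    coefficient spread exceeds ``coeff_hi / coeff_lo`` are resampled.
    """
    if not coeff_lo < coeff_hi:
        raise ConfigurationError("coeff_lo must be < coeff_hi")
    rng = np.random.default_rng(seed)
    shapes = config.layer_shapes()
    for _ in range(max_attempts):
        weights, biases = [], []
        for (wshape, bsize) in shapes:
            mag = rng.uniform(0.5, 1.5, size=wshape)
            sgn = rng.choice([-1.0, 1.0], size=wshape)
            weights.append(mag * sgn)
            magb = rng.uniform(0.5, 1.5, size=bsize)
            sgnb = rng.choice([-1.0, 1.0], size=bsize)
            biases.append(magb * sgnb)
        params = PiNetParams(weights, biases)
        mags = np.abs(expand_to_polynomial(params, config).coeffs)
        cmax, cmin = mags.max(), mags.min()
        if cmin == 0.0 or cmax / cmin > coeff_hi / coeff_lo:
            continue
        # centre the band geometrically: scale read-out so magnitudes fit
        target = np.sqrt(coeff_lo * coeff_hi)
        gamma = target / np.sqrt(cmax * cmin)
        params.weights[-1] = params.weights[-1] * gamma
        mags = np.abs(expand_to_polynomial(params, config).coeffs)
        if mags.max() <= coeff_hi and mags.min() >= coeff_lo:
            return params
    raise InitializationError(
        f"could not place expanded coefficients in [{coeff_lo:g}, {coeff_hi:g}] "
        f"after {max_attempts} attempts"
    )
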