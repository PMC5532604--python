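"""Pólya-Gamma random variate generation.

The PG(b, c) distribution is the workhorse of conjugate data augmentation for
logistic-type likelihoods: if omega ~ PG(b, c) then the logistic likelihood
admits a conditionally Gaussian representation.  Draws for integer shape b are
exact: PG(b, c) is the b-fold convolution of PG(1, c), and PG(1, c) is sampled
with Devroye's alternating-series rejection algorithm.

Useful closed forms used by the test suite:

    E[omega | b, c]   = (b / (2 c)) * tanh(c / 2)
    Var[omega | b, c] = (b / (4 c^3)) * (sinh(c) - c) / cosh(c / 2)^2

The hot loop is compiled with numba; reproducibility is obtained by seeding
numba's internal RNG explicitly on every vectorised call.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["polya_gamma", "pg_mean", "pg_var"]

_TRUNC = 0.64  # Devroye's crossover point between the two series kernels


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _pigauss_cdf(x, z, lam):
    """CDF at x of inverse-Gaussian(mu = 1/z, lambda = lam), stable for z -> 0."""
    if x <= 0.0:
        return 0.0
    s = math.sqrt(lam / x)
    # written in terms of z = 1/mu so the z = 0 (Levy) limit is exact
    return _norm_cdf(s * (x * z - 1.0)) + math.exp(2.0 * lam * z) * _norm_cdf(
        -s * (x * z + 1.0)
    )


@njit(cache=True)
def _rtigauss(z, t):
    """Inverse-Gaussian(mu = 1/z, lambda = 1) truncated to (0, t)."""
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection sample from the Levy-like tail
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential()
            e2 = np.random.exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential()
                e2 = np.random.exponential()
            x = t / ((1.0 + t * e1) ** 2)
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.normal() ** 2
            muy = mu * y
            x = mu * (1.0 + 0.5 * muy - 0.5 * math.sqrt(4.0 * muy + muy * muy))
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _series_coef(n, x, t):
    """Devroye's a_n(x) coefficients of the alternating series."""
    h = n + 0.5
    if x <= t:
        return (
            math.pi
            * h
            * math.pow(2.0 / (math.pi * x), 1.5)
            * math.exp(-2.0 * h * h / x)
        )
    return math.pi * h * math.exp(-h * h * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _jacobi_one(z):
    """One draw of J*(1, z); PG(1, c) = J*(1, c/2) / 4."""
    t = _TRUNC
    z = abs(z)
    k = math.pi * math.pi / 8.0 + z * z / 2.0
    p = (math.pi / (2.0 * k)) * math.exp(-k * t)
    q = 2.0 * math.exp(-z) * _pigauss_cdf(t, z, 1.0)

    while True:
        u = np.random.random()
        if u < p / (p + q):
            x = t + np.random.exponential() / k
        else:
            x = _rtigauss(z, t)
        # squeeze with the alternating series of the Jacobi density
        s = _series_coef(0, x, t)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _series_coef(n, x, t)
                if y <= s:
                    return x
            else:
                s += _series_coef(n, x, t)
                if y > s:
                    break  # reject, restart outer loop


@njit(cache=True)
def _pg_fill(b, c, seed, out):
    np.random.seed(seed)
    for i in range(out.size):
        total = 0.0
        half_c = c[i] / 2.0
        for _ in range(b[i]):
            total += _jacobi_one(half_c)
        out[i] = total / 4.0


def polya_gamma(b, c, rng):
    """Draw PG(b_i, c_i) for paired integer shapes and tilts.

    Parameters
    ----------
    b : array-like of non-negative ints
        Shape parameters (b = 0 yields a deterministic 0).
    c : array-like of float
        Tilt parameters, broadcast against ``b``.
    rng : numpy.random.Generator
        Source of the seed for the compiled kernel.
    """
    b = np.asarray(b)
    c = np.asarray(c, dtype=np.float64)
    b, c = np.broadcast_arrays(b, c)
    b = np.ascontiguousarray(b, dtype=np.int64)
    c = np.ascontiguousarray(c, dtype=np.float64)
    if np.any(b < 0):
        raise ValueError("PG shape parameters must be non-negative integers")
    out = np.empty(b.shape, dtype=np.float64)
    seed = int(rng.integers(0, 2**31 - 1))
    _pg_fill(b.ravel(), c.ravel(), seed, out.ravel())
    return out


def pg_mean(b, c):
    """E[omega] for omega ~ PG(b, c); continuous at c = 0 (value b/4)."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(np.abs(c) < 1e-8, b / 4.0, b / (2.0 * c) * np.tanh(c / 2.0))
    return m


def pg_var(b, c):
    """Var[omega] for omega ~ PG(b, c); limit b/24 at c = 0."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(
            np.abs(c) < 1e-4,
            b / 24.0,
            b / (4.0 * c**3) * (np.sinh(c) - c) / np.cosh(c / 2.0) ** 2,
        )
    return v
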