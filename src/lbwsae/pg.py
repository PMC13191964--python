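"""Exact Pólya-Gamma PG(b, z) sampling for logistic data augmentation.

Implements the alternating-series rejection sampler for PG(1, z) (Devroye's
method for the Jacobi J*(1, z) density, with exponential and inverse-Gaussian
proposals split at t = 0.64) and sums independent PG(1, z) draws for integer
b. The sampler is exact, not approximate; it is written as a scalar loop and
intended for the modest cluster counts of the full-Gibbs cross-check sampler
rather than for very large augmentation problems.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["polya_gamma"]

_T = 0.64  # proposal split point of the J*(1, z) sampler
_HALF_PI2 = math.pi * math.pi / 8.0


def _coef(n: int, x: float) -> float:
    """n-th term a_n(x) of the alternating series for the J*(1,.) density."""
    h = n + 0.5
    if x <= _T:
        return math.pi * h * math.pow(2.0 / (math.pi * x), 1.5) * math.exp(-2.0 * h * h / x)
    return math.pi * h * math.exp(-h * h * math.pi * math.pi * x / 2.0)


def _norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def _trunc_inv_gauss(z: float, rng: np.random.Generator) -> float:
    """Draw from InverseGaussian(mu=1/z, lambda=1) truncated to (0, _T]."""
    t = _T
    if z < 1.0 / t:  # mu > t: rejection from the z=0 (one-sided stable) body
        while True:
            while True:
                e1 = rng.exponential()
                e2 = rng.exponential()
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) ** 2)
            if rng.random() <= math.exp(-0.5 * z * z * x):
                return x
    mu = 1.0 / z
    while True:
        y = rng.standard_normal() ** 2
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
        if rng.random() > mu / (mu + x):
            x = mu * mu / x
        if x <= t:
            return x


def _pg1(z: float, rng: np.random.Generator) -> float:
    """One exact draw of PG(1, z)."""
    z = abs(z) / 2.0
    k = _HALF_PI2 + z * z / 2.0
    p = (math.pi / (2.0 * k)) * math.exp(-k * _T)
    # mass of the inverse-Gaussian proposal on (0, t]:
    # 2 e^{-z} P(IG(1/z, 1) <= t), written via the IG cdf in normal cdfs
    sqt = math.sqrt(_T)
    q = 2.0 * (
        math.exp(-z) * _norm_cdf((z * _T - 1.0) / sqt)
        + math.exp(z) * _norm_cdf(-(z * _T + 1.0) / sqt)
    ) if z > 0 else 4.0 * _norm_cdf(-1.0 / sqt)
    ratio = p / (p + q)
    while True:
        if rng.random() < ratio:
            x = _T + rng.exponential() / k
        else:
            x = _trunc_inv_gauss(z, rng)
        s = _coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _coef(n, x)
                if y <= s:
                    return x / 4.0
            else:
                s += _coef(n, x)
                if y > s:
                    break  # reject; draw a new proposal


def polya_gamma(b, z, rng: np.random.Generator) -> np.ndarray:
    """Draw PG(b_i, z_i) elementwise for integer shapes b and reals z.

    PG(b, z) with integer b is the sum of b independent PG(1, z) variables.
    Returns an array shaped like the broadcast of ``b`` and ``z``.
    """
    b_arr = np.atleast_1d(np.asarray(b, dtype=np.int64))
    z_arr = np.atleast_1d(np.asarray(z, dtype=np.float64))
    b_arr, z_arr = np.broadcast_arrays(b_arr, z_arr)
    if np.any(b_arr < 0):
        raise ValueError("Polya-Gamma shape b must be a non-negative integer")
    out = np.empty(b_arr.shape, dtype=np.float64)
    flat_b = b_arr.ravel()
    flat_z = z_arr.ravel()
    flat_o = out.ravel()
    for i in range(flat_b.size):
        acc = 0.0
        for _ in range(int(flat_b[i])):
            acc += _pg1(float(flat_z[i]), rng)
        flat_o[i] = acc
    return out
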