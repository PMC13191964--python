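"""Deterministic quadrature posterior for tiny reduced models.

For an instance with a single state and district (both variance components
pinned to 0) and a small number of clusters with known cluster variance,
the posterior over (beta0, u_1..u_K) is low-dimensional and can be
integrated numerically on a dense tensor grid. Used as an independent check
of the MCMC samplers; shares nothing with their code paths beyond the
Bernoulli likelihood formula.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["quadrature_posterior"]


def quadrature_posterior(
    y,
    n,
    sigma2_u: float,
    beta0_range: tuple[float, float] = (-9.0, 6.0),
    n_beta0: int = 301,
    n_u: int = 201,
    u_halfwidth_sd: float = 6.0,
):
    """Posterior means/sds of beta0 and cluster effects by grid integration.

    ``y``/``n`` are per-cluster successes and trials (at most 3 clusters —
    the tensor grid grows exponentially). Prior: flat on beta0,
    u_j ~ N(0, sigma2_u). Returns a dict with ``beta0_mean``, ``beta0_sd``,
    ``u_mean``/``u_sd`` (arrays) and ``p_mean`` — the posterior mean of
    invlogit(beta0 + u_j) per cluster, i.e. the cluster-level predicted
    probability that shrinkage checks compare against.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    k = y.size
    if k > 3:
        raise ValueError("quadrature oracle supports at most 3 clusters")
    if sigma2_u <= 0:
        raise ValueError("sigma2_u must be > 0")

    b = np.linspace(*beta0_range, n_beta0)
    su = math.sqrt(sigma2_u)
    ug = np.linspace(-u_halfwidth_sd * su, u_halfwidth_sd * su, n_u)

    axes = [b] + [ug] * k
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    logw = np.zeros(tuple(n_beta0 if i == 0 else n_u for i in range(k + 1)))
    for j in range(k):
        eta = grids[0] + grids[j + 1]
        logw = logw + y[j] * eta - n[j] * np.logaddexp(0.0, eta)
        logw = logw - grids[j + 1] ** 2 / (2.0 * sigma2_u)
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()

    def moments(axis_grid, axis):
        shape = [1] * (k + 1)
        shape[axis] = -1
        g = axis_grid.reshape(shape)
        m1 = float((w * g).sum() / total)
        m2 = float((w * g * g).sum() / total)
        return m1, math.sqrt(max(m2 - m1 * m1, 0.0))

    b_mean, b_sd = moments(b, 0)
    u_mean = np.empty(k)
    u_sd = np.empty(k)
    p_mean = np.empty(k)
    for j in range(k):
        u_mean[j], u_sd[j] = moments(ug, j + 1)
        shape_b = [1] * (k + 1)
        shape_b[0] = -1
        shape_u = [1] * (k + 1)
        shape_u[j + 1] = -1
        eta = b.reshape(shape_b) + ug.reshape(shape_u)
        p = 1.0 / (1.0 + np.exp(-eta))
        p_mean[j] = float((w * p).sum() / total)
    return {
        "beta0_mean": b_mean,
        "beta0_sd": b_sd,
        "u_mean": u_mean,
        "u_sd": u_sd,
        "p_mean": p_mean,
    }
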