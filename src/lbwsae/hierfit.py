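"""Four-level random-intercept logistic model fitted by MCMC.

The model for birth i in cluster j, district k, state l is

    Y_ijkl ~ Bernoulli(p_jkl),  logit(p_jkl) = beta0 + u_jkl + v_kl + f_l

with u ~ N(0, sigma2_u), v ~ N(0, sigma2_v), f ~ N(0, sigma2_f). There are
no covariates, so all births in a cluster share one linear predictor and the
likelihood reduces exactly to per-cluster binomial sufficient statistics
(y_j successes out of n_j births); the samplers operate on those.

Priors follow the convention of the multilevel-modelling software this kind
of analysis is usually run in: an improper flat prior on beta0 and
InverseGamma(0.001, 0.001) on each free variance component.

Two samplers are provided:

* ``"mh"`` (default): Metropolis-within-Gibbs. Adaptive random-walk MH for
  beta0 and for each residual block (clusters, districts and states update
  element-wise in parallel since they are conditionally independent),
  conjugate inverse-gamma Gibbs draws for the variances, plus
  likelihood-invariant translation moves that shift mass between beta0 and
  a whole residual vector and are accepted on the prior ratio alone. The
  translation moves cure the slow random walk the intercept would otherwise
  perform against the sum of the state intercepts. Proposal scales adapt
  toward 0.44 acceptance during burn-in only, so the stored draws form a
  valid Markov chain.
* ``"pg"``: full Gibbs via exact Pólya-Gamma augmentation; no tuning. Kept
  as an independent cross-check of the default sampler.

Variance components can be pinned with ``FitConfig.fixed_sigma2``; pinning a
component to 0 removes that level entirely (its residuals stay 0), pinning
to a positive value keeps the residuals but skips the variance update. This
is what makes tiny instances tractable for deterministic quadrature checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "FitConfig",
    "PosteriorDraws",
    "DiagnosticsReport",
    "log_likelihood",
    "starting_values",
    "fit_mcmc",
    "diagnose",
]

_LOGIT_CLAMP = 1e-6


@dataclass
class ModelParams:
    """Intercept (log-odds) and the three variance components (log-odds^2)."""

    beta0: float
    sigma2_u: float
    sigma2_v: float
    sigma2_f: float


@dataclass
class FitConfig:
    """MCMC settings.

    ``fixed_sigma2`` maps level names (``"u"``, ``"v"``, ``"f"``) to pinned
    variance values; 0 removes the level. ``prior_shape``/``prior_rate`` are
    the InverseGamma hyperparameters shared by all free variances.
    """

    n_burnin: int = 500
    n_iter: int = 5000
    thin: int = 1
    sampler: str = "mh"
    prior_shape: float = 0.001
    prior_rate: float = 0.001
    init_sigma2: float = 0.1
    seed: int | None = None
    fixed_sigma2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.sampler not in ("mh", "pg"):
            raise ValueError(f"unknown sampler {self.sampler!r}; use 'mh' or 'pg'")
        for k, val in self.fixed_sigma2.items():
            if k not in ("u", "v", "f"):
                raise ValueError(f"fixed_sigma2 keys must be 'u','v','f', got {k!r}")
            if val < 0:
                raise ValueError("fixed variances must be >= 0")


@dataclass
class PosteriorDraws:
    """Post burn-in draws of all model unknowns plus index metadata.

    Residual matrices are (n_draws, n_units), stored float32; the id arrays
    give the canonical (sorted) unit order the columns refer to.
    ``cluster_district`` / ``cluster_state`` / ``district_state`` are integer
    index maps into the district and state axes.
    """

    beta0: np.ndarray
    sigma2_u: np.ndarray
    sigma2_v: np.ndarray
    sigma2_f: np.ndarray
    u: np.ndarray
    v: np.ndarray
    f: np.ndarray
    cluster_ids: np.ndarray
    district_ids: np.ndarray
    state_ids: np.ndarray
    cluster_district: np.ndarray
    cluster_state: np.ndarray
    district_state: np.ndarray
    meta: dict

    @property
    def n_draws(self) -> int:
        return int(self.beta0.shape[0])

    def params_mean(self) -> ModelParams:
        return ModelParams(
            beta0=float(self.beta0.mean()),
            sigma2_u=float(self.sigma2_u.mean()),
            sigma2_v=float(self.sigma2_v.mean()),
            sigma2_f=float(self.sigma2_f.mean()),
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per scalar parameter."""
        rows = []
        for name in ("beta0", "sigma2_u", "sigma2_v", "sigma2_f"):
            x = getattr(self, name)
            lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
            rows.append(
                dict(param=name, mean=float(x.mean()), sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                     q2_5=float(lo), median=float(med), q97_5=float(hi))
            )
        return pd.DataFrame(rows)


@dataclass
class DiagnosticsReport:
    """Per-parameter effective sample size and split-chain shrink factor."""

    table: pd.DataFrame
    flags: list


# ---------------------------------------------------------------------------
# data preparation


class _Structure:
    """Canonical sorted index structure and binomial sufficient statistics."""

    def __init__(self, data: pd.DataFrame):
        required = {"state_id", "district_id", "cluster_id", "lbw"}
        missing_cols = required - set(data.columns)
        if missing_cols:
            raise ValueError(f"survey data lacks columns: {sorted(missing_cols)}")
        if len(data) == 0:
            raise ValueError("survey data is empty")
        if data["lbw"].isna().any():
            raise ValueError(
                "survey data contains missing lbw values; run apply_exclusions first"
            )
        if "wave" in data.columns:
            waves = data["wave"].unique()
            if len(waves) > 1:
                raise ValueError(
                    f"fit one wave at a time; data contains waves {sorted(map(str, waves))}"
                )
            self.wave = str(waves[0])
        else:
            self.wave = ""

        grp = (
            data.assign(lbw=data["lbw"].astype("int64"))
            .groupby(["state_id", "district_id", "cluster_id"], sort=True)["lbw"]
            .agg(["sum", "count"])
            .reset_index()
        )
        # a cluster id may not sit under two districts
        dup = grp["cluster_id"].duplicated(keep=False)
        if dup.any():
            bad = grp.loc[dup, "cluster_id"].iloc[0]
            raise ValueError(f"cluster {bad!r} appears under more than one district/state")

        self.y = grp["sum"].to_numpy(dtype=np.float64)
        self.n = grp["count"].to_numpy(dtype=np.float64)
        self.cluster_ids = grp["cluster_id"].to_numpy(dtype=object)

        dist = grp[["state_id", "district_id"]].drop_duplicates().sort_values(
            ["state_id", "district_id"], kind="mergesort"
        )
        ddup = dist["district_id"].duplicated(keep=False)
        if ddup.any():
            bad = dist.loc[ddup, "district_id"].iloc[0]
            raise ValueError(f"district {bad!r} appears under more than one state")
        self.district_ids = dist["district_id"].to_numpy(dtype=object)
        self.state_ids = np.unique(data["state_id"].to_numpy(dtype=object))

        d_index = {d: i for i, d in enumerate(self.district_ids)}
        s_index = {s: i for i, s in enumerate(self.state_ids)}
        self.cluster_district = grp["district_id"].map(d_index).to_numpy(dtype=np.int64)
        self.district_state = dist["state_id"].map(s_index).to_numpy(dtype=np.int64)
        self.cluster_state = self.district_state[self.cluster_district]
        self.J = len(self.cluster_ids)
        self.D = len(self.district_ids)
        self.S = len(self.state_ids)


def _cluster_loglik(y, n, eta):
    """Vector of binomial Bernoulli log-likelihood contributions per cluster."""
    return y * eta - n * np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# public operations


def log_likelihood(data: pd.DataFrame, params: ModelParams,
                   residuals: Mapping[str, Mapping[str, float]]) -> float:
    """Bernoulli log-likelihood of the data at given parameters and residuals.

    ``residuals`` maps ``"u"``/``"v"``/``"f"`` to {identifier: value} dicts
    keyed by cluster, district and state ids respectively. Every unit present
    in the data must be covered; the first unmatched identifier is named in
    the error.
    """
    st = _Structure(data)
    out = {}
    for level, ids in (("u", st.cluster_ids), ("v", st.district_ids), ("f", st.state_ids)):
        table = residuals.get(level, {})
        vals = np.empty(len(ids))
        for i, ident in enumerate(ids):
            if ident not in table:
                raise KeyError(f"residual vector {level!r} lacks an entry for {ident!r}")
            vals[i] = table[ident]
        out[level] = vals
    eta = (params.beta0 + out["u"] + out["v"][st.cluster_district]
           + out["f"][st.cluster_state])
    return float(_cluster_loglik(st.y, st.n, eta).sum())


def starting_values(data: pd.DataFrame) -> tuple[ModelParams, dict]:
    """Pooled-logit starting point: beta0 = logit(overall prevalence).

    Variances start at a small positive constant and all residuals at zero —
    a stand-in for a preliminary frequentist fit, affecting only how fast
    the chain reaches its stationary distribution, not the posterior.
    """
    st = _Structure(data)
    prev = float(st.y.sum() / st.n.sum())
    clamped = min(max(prev, _LOGIT_CLAMP), 1.0 - _LOGIT_CLAMP)
    if clamped != prev:
        warnings.warn(
            f"pooled prevalence {prev:.4g} clamped to {clamped:.4g} before logit",
            RuntimeWarning,
            stacklevel=2,
        )
    params = ModelParams(beta0=math.log(clamped / (1.0 - clamped)),
                         sigma2_u=0.1, sigma2_v=0.1, sigma2_f=0.1)
    residuals = {
        "u": {c: 0.0 for c in st.cluster_ids},
        "v": {d: 0.0 for d in st.district_ids},
        "f": {s: 0.0 for s in st.state_ids},
    }
    return params, residuals


def fit_mcmc(data: pd.DataFrame, config: FitConfig | None = None) -> PosteriorDraws:
    """Sample the posterior of (beta0, variances, residuals) by MCMC.

    Input is single-wave, complete-case microdata under the survey contract.
    The chain is reproducible for a fixed seed, and row order of the input is
    irrelevant because units are canonicalised by sorted identifier.
    """
    config = config or FitConfig()
    st = _Structure(data)
    if st.S < 2 or st.D <= st.S or st.J <= st.D:
        warnings.warn(
            "hierarchy is shallow (need >=2 states and >=2 units within some parent "
            "for each level); variance components may be weakly identified",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    if config.sampler == "mh":
        return _fit_mh(st, config, rng)
    return _fit_pg(st, config, rng)


# ---------------------------------------------------------------------------
# samplers

_LEVELS = ("u", "v", "f")


def _level_setup(st, config):
    sizes = {"u": st.J, "v": st.D, "f": st.S}
    fixed = dict(config.fixed_sigma2)
    active = {lvl: fixed.get(lvl, None) != 0.0 for lvl in _LEVELS}
    free_var = {lvl: lvl not in fixed for lvl in _LEVELS}
    return sizes, fixed, active, free_var


def _init_state(st, config, fixed):
    prev = float(st.y.sum() / st.n.sum())
    prev = min(max(prev, _LOGIT_CLAMP), 1.0 - _LOGIT_CLAMP)
    beta0 = math.log(prev / (1.0 - prev))
    sig = {lvl: float(fixed.get(lvl, config.init_sigma2)) for lvl in _LEVELS}
    res = {"u": np.zeros(st.J), "v": np.zeros(st.D), "f": np.zeros(st.S)}
    return beta0, sig, res


def _eta(st, beta0, res):
    return (beta0 + res["u"] + res["v"][st.cluster_district]
            + res["f"][st.cluster_state])


def _alloc_store(st, config):
    n_keep = (config.n_iter + config.thin - 1) // config.thin
    return {
        "beta0": np.empty(n_keep),
        "sigma2_u": np.empty(n_keep),
        "sigma2_v": np.empty(n_keep),
        "sigma2_f": np.empty(n_keep),
        "u": np.empty((n_keep, st.J), dtype=np.float32),
        "v": np.empty((n_keep, st.D), dtype=np.float32),
        "f": np.empty((n_keep, st.S), dtype=np.float32),
    }


def _package(st, config, store, kept, accept, total, extra_meta=None):
    meta = {
        "n_burnin": config.n_burnin,
        "n_iter": config.n_iter,
        "thin": config.thin,
        "n_draws": kept,
        "sampler": config.sampler,
        "seed": config.seed,
        "wave": st.wave,
        "fixed_sigma2": dict(config.fixed_sigma2),
        "acceptance": {k: (accept[k] / total if total else float("nan")) for k in accept},
    }
    if extra_meta:
        meta.update(extra_meta)
    return PosteriorDraws(
        beta0=store["beta0"][:kept],
        sigma2_u=store["sigma2_u"][:kept],
        sigma2_v=store["sigma2_v"][:kept],
        sigma2_f=store["sigma2_f"][:kept],
        u=store["u"][:kept],
        v=store["v"][:kept],
        f=store["f"][:kept],
        cluster_ids=st.cluster_ids,
        district_ids=st.district_ids,
        state_ids=st.state_ids,
        cluster_district=st.cluster_district,
        cluster_state=st.cluster_state,
        district_state=st.district_state,
        meta=meta,
    )


def _draw_inv_gamma(rng, shape, rate):
    return rate / rng.gamma(shape)


def _fit_mh(st, config, rng):
    sizes, fixed, active, free_var = _level_setup(st, config)
    beta0, sig, res = _init_state(st, config, fixed)
    group_idx = {"u": None, "v": st.cluster_district, "f": st.cluster_state}

    scales = {"beta0": 0.2, "u": 0.5, "v": 0.5, "f": 0.5,
              "t_u": 0.1, "t_v": 0.1, "t_f": 0.1}
    store = _alloc_store(st, config)
    accept = {k: 0.0 for k in ("beta0", "u", "v", "f", "t_u", "t_v", "t_f")}
    kept = 0
    post_iters = 0

    eta = _eta(st, beta0, res)
    ll = _cluster_loglik(st.y, st.n, eta)

    def adapt(name, rate, it):
        gamma = min(0.25, 2.0 / math.sqrt(it + 1))
        scales[name] *= math.exp(gamma * (rate - 0.44))
        scales[name] = min(max(scales[name], 1e-4), 50.0)

    n_total = config.n_burnin + config.n_iter
    for it in range(n_total):
        burnin = it < config.n_burnin

        # --- beta0 random walk
        delta = scales["beta0"] * rng.standard_normal()
        ll_new = _cluster_loglik(st.y, st.n, eta + delta)
        acc = math.log(rng.random()) < ll_new.sum() - ll.sum()
        if acc:
            beta0 += delta
            eta = eta + delta
            ll = ll_new
        if burnin:
            adapt("beta0", float(acc), it)
        else:
            accept["beta0"] += acc
            post_iters += 1

        # --- translation moves: beta0 <-> whole residual vector, likelihood
        # invariant, accepted on the shifted Gaussian prior alone
        for lvl in _LEVELS:
            if not active[lvl]:
                continue
            name = f"t_{lvl}"
            dlt = scales[name] * rng.standard_normal()
            r = res[lvl]
            logr = -((r - dlt) ** 2 - r ** 2).sum() / (2.0 * sig[lvl])
            acc = math.log(rng.random()) < logr
            if acc:
                beta0 += dlt
                res[lvl] = r - dlt
            if burnin:
                adapt(name, float(acc), it)
            else:
                accept[name] += acc

        # --- element-wise random-walk updates per level (conditionally
        # independent within a level, so accept/reject vectorises)
        for lvl in _LEVELS:
            if not active[lvl]:
                continue
            r = res[lvl]
            m = r.size
            step = scales[lvl] * rng.standard_normal(m)
            if lvl == "u":
                dll = _cluster_loglik(st.y, st.n, eta + step) - ll
            else:
                idx = group_idx[lvl]
                dll_c = _cluster_loglik(st.y, st.n, eta + step[idx]) - ll
                dll = np.bincount(idx, weights=dll_c, minlength=m)
            dlp = -(2.0 * r * step + step ** 2) / (2.0 * sig[lvl])
            acc_mask = np.log(rng.random(m)) < dll + dlp
            if acc_mask.any():
                res[lvl] = r + step * acc_mask
                if lvl == "u":
                    eta = eta + step * acc_mask
                else:
                    eta = eta + (step * acc_mask)[group_idx[lvl]]
                ll = _cluster_loglik(st.y, st.n, eta)
            rate = float(acc_mask.mean())
            if burnin:
                adapt(lvl, rate, it)
            else:
                accept[lvl] += rate

        # --- conjugate variance updates
        for lvl in _LEVELS:
            if active[lvl] and free_var[lvl]:
                r = res[lvl]
                sig[lvl] = float(_draw_inv_gamma(
                    rng,
                    config.prior_shape + r.size / 2.0,
                    config.prior_rate + 0.5 * float(r @ r),
                ))

        if not burnin and (it - config.n_burnin) % config.thin == 0:
            store["beta0"][kept] = beta0
            store["sigma2_u"][kept] = sig["u"]
            store["sigma2_v"][kept] = sig["v"]
            store["sigma2_f"][kept] = sig["f"]
            store["u"][kept] = res["u"]
            store["v"][kept] = res["v"]
            store["f"][kept] = res["f"]
            kept += 1

    return _package(st, config, store, kept, accept, post_iters,
                    extra_meta={"proposal_scales": dict(scales)})


def _fit_pg(st, config, rng):
    from .pg import polya_gamma

    sizes, fixed, active, free_var = _level_setup(st, config)
    beta0, sig, res = _init_state(st, config, fixed)
    kappa = st.y - st.n / 2.0
    n_int = st.n.astype(np.int64)
    store = _alloc_store(st, config)
    kept = 0

    n_total = config.n_burnin + config.n_iter
    for it in range(n_total):
        eta = _eta(st, beta0, res)
        omega = polya_gamma(n_int, eta, rng)

        # beta0 | omega (flat prior)
        rest = res["u"] + res["v"][st.cluster_district] + res["f"][st.cluster_state]
        prec = omega.sum()
        mean = float((kappa - omega * rest).sum()) / prec
        beta0 = mean + rng.standard_normal() / math.sqrt(prec)

        if active["u"]:
            other = beta0 + res["v"][st.cluster_district] + res["f"][st.cluster_state]
            p_u = omega + 1.0 / sig["u"]
            m_u = (kappa - omega * other) / p_u
            res["u"] = m_u + rng.standard_normal(st.J) / np.sqrt(p_u)

        if active["v"]:
            other = beta0 + res["u"] + res["f"][st.cluster_state]
            num = np.bincount(st.cluster_district, weights=kappa - omega * other,
                              minlength=st.D)
            p_v = np.bincount(st.cluster_district, weights=omega, minlength=st.D) + 1.0 / sig["v"]
            res["v"] = num / p_v + rng.standard_normal(st.D) / np.sqrt(p_v)

        if active["f"]:
            other = beta0 + res["u"] + res["v"][st.cluster_district]
            num = np.bincount(st.cluster_state, weights=kappa - omega * other,
                              minlength=st.S)
            p_f = np.bincount(st.cluster_state, weights=omega, minlength=st.S) + 1.0 / sig["f"]
            res["f"] = num / p_f + rng.standard_normal(st.S) / np.sqrt(p_f)

        for lvl in _LEVELS:
            if active[lvl] and free_var[lvl]:
                r = res[lvl]
                sig[lvl] = float(_draw_inv_gamma(
                    rng,
                    config.prior_shape + r.size / 2.0,
                    config.prior_rate + 0.5 * float(r @ r),
                ))

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            store["beta0"][kept] = beta0
            store["sigma2_u"][kept] = sig["u"]
            store["sigma2_v"][kept] = sig["v"]
            store["sigma2_f"][kept] = sig["f"]
            store["u"][kept] = res["u"]
            store["v"][kept] = res["v"]
            store["f"][kept] = res["f"]
            kept += 1

    accept = {"gibbs": float(kept > 0)}
    return _package(st, config, store, kept, accept, 1)


# ---------------------------------------------------------------------------
# diagnostics


def diagnose(draws: PosteriorDraws, ess_flag: float = 100.0) -> DiagnosticsReport:
    """Effective sample size and split-chain R-hat per scalar parameter.

    A parameter is flagged when its ESS falls below ``ess_flag`` or the
    chain is numerically constant (degenerate).
    """
    import arviz as az

    if draws.n_draws < 2:
        raise ValueError("diagnostics need at least 2 stored draws")
    rows, flags = [], []
    for name in ("beta0", "sigma2_u", "sigma2_v", "sigma2_f"):
        x = np.asarray(getattr(draws, name), dtype=np.float64)
        if np.ptp(x) == 0.0:
            rows.append(dict(param=name, ess=0.0, rhat=np.nan, degenerate=True))
            flags.append(f"{name}: degenerate (constant chain)")
            continue
        half = x.size // 2
        two = x[: 2 * half].reshape(2, half)
        ess = float(az.ess(x[None, :]))
        rhat = float(az.rhat(two)) if half >= 2 else np.nan
        rows.append(dict(param=name, ess=ess, rhat=rhat, degenerate=False))
        if ess < ess_flag:
            flags.append(f"{name}: ESS {ess:.1f} < {ess_flag:g}")
    return DiagnosticsReport(table=pd.DataFrame(rows), flags=flags)
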