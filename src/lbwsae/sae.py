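"""Small-area prediction: precision-weighted cluster probabilities and
district prevalences.

The multilevel posterior shrinks each cluster's intercept toward its
district (and further toward state and national) mean in proportion to how
informative its data are — the "precision weighting". The cluster-level
predicted probability is the posterior mean over MCMC draws of
invlogit(beta0 + u_jkl + v_kl + f_l); district prevalence is the simple
(unweighted) average of its member clusters' probabilities, in percent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierfit import PosteriorDraws

__all__ = ["cluster_probabilities", "district_prevalence"]


def cluster_probabilities(
    draws: PosteriorDraws,
    method: str = "mean_prob",
    chunk: int = 256,
) -> pd.DataFrame:
    """Per-cluster predicted LBW probability with posterior SD.

    ``method="mean_prob"`` (default) averages the per-draw probabilities —
    the posterior mean of the target functional. ``method="plugin"``
    instead applies invlogit to the posterior-mean linear predictor; the two
    differ by Jensen's inequality and both are exposed.

    Returns a frame with columns
    ``cluster_id, district_id, state_id, wave, p_hat, p_sd, n_draws``.
    """
    if draws.n_draws < 1:
        raise ValueError("posterior contains no draws")
    if method not in ("mean_prob", "plugin"):
        raise ValueError(f"unknown method {method!r}")

    j = draws.cluster_ids.size
    s1 = np.zeros(j)
    s2 = np.zeros(j)
    eta_sum = np.zeros(j)
    for lo in range(0, draws.n_draws, chunk):
        hi = min(lo + chunk, draws.n_draws)
        eta = (
            draws.beta0[lo:hi, None]
            + draws.u[lo:hi].astype(np.float64)
            + draws.v[lo:hi].astype(np.float64)[:, draws.cluster_district]
            + draws.f[lo:hi].astype(np.float64)[:, draws.cluster_state]
        )
        p = expit(eta)
        s1 += p.sum(axis=0)
        s2 += (p * p).sum(axis=0)
        eta_sum += eta.sum(axis=0)

    m = s1 / draws.n_draws
    var = np.maximum(s2 / draws.n_draws - m * m, 0.0)
    p_hat = m if method == "mean_prob" else expit(eta_sum / draws.n_draws)
    return pd.DataFrame(
        {
            "cluster_id": draws.cluster_ids,
            "district_id": draws.district_ids[draws.cluster_district],
            "state_id": draws.state_ids[draws.cluster_state],
            "wave": draws.meta.get("wave", ""),
            "p_hat": np.clip(p_hat, 0.0, 1.0),
            "p_sd": np.sqrt(var),
            "n_draws": draws.n_draws,
        }
    )


def district_prevalence(
    clusters: pd.DataFrame,
    crosswalk: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """District prevalence (%) as the unweighted mean of cluster p_hats.

    ``crosswalk``, when given, reassigns clusters to districts (columns
    ``cluster_id, district_id`` and optionally ``wave``); by default each
    cluster's own ``district_id`` is used (identity crosswalk). Every
    cluster must map to exactly one district; districts named in the
    crosswalk but holding no clusters are omitted with a warning.

    Returns ``district_id, state_id, wave, prevalence_pct, n_clusters``.
    """
    df = clusters.drop_duplicates(subset=["cluster_id", "wave"]).copy()
    if crosswalk is not None:
        cw = crosswalk.copy()
        keys = ["cluster_id", "wave"] if "wave" in cw.columns else ["cluster_id"]
        dup = cw.duplicated(subset=keys, keep=False)
        if dup.any():
            bad = cw.loc[dup, "cluster_id"].iloc[0]
            raise ValueError(f"crosswalk maps cluster {bad!r} to multiple districts")
        mapping = cw.set_index(keys)["district_id"]
        idx = pd.MultiIndex.from_frame(df[keys]) if len(keys) == 2 else df["cluster_id"]
        mapped = mapping.reindex(idx)
        if mapped.isna().any():
            bad = df.loc[np.asarray(mapped.isna()), "cluster_id"].iloc[0]
            raise KeyError(f"cluster {bad!r} has no crosswalk entry")
        df["district_id"] = np.asarray(mapped)
        empties = set(cw["district_id"]) - set(df["district_id"])
        if empties:
            warnings.warn(
                f"{len(empties)} crosswalk district(s) hold no clusters and are omitted "
                f"(e.g. {sorted(empties)[0]!r})",
                RuntimeWarning,
                stacklevel=2,
            )

    grp = (
        df.groupby(["district_id", "wave"], sort=True)
        .agg(
            state_id=("state_id", "first"),
            prevalence_pct=("p_hat", lambda s: 100.0 * float(np.mean(s))),
            n_clusters=("p_hat", "size"),
        )
        .reset_index()
    )
    return grp[["district_id", "state_id", "wave", "prevalence_pct", "n_clusters"]]
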