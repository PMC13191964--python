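"""Synthetic two-wave NFHS-like survey generator.

Emulates the hierarchical structure of DHS-style cluster surveys of live
births: individual births (level 1) nested in clusters / primary sampling
units (level 2), districts (level 3) and states (level 4). Each level
contributes a normal random intercept on the log-odds scale; the binary
outcome is a low-birth-weight (LBW) indicator, and records are made missing
completely at random at a configurable rate to mimic incomplete birth-weight
reporting.

Ground-truth random effects are kept in a sidecar table, never in the survey
file itself, so that fitting code cannot accidentally read the truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GeneratorConfig",
    "GeneratedSurvey",
    "ExclusionReport",
    "generate_survey",
    "apply_exclusions",
    "india_preset",
    "sample_adp_districts",
    "write_survey",
    "read_survey",
    "INDIA_STATES",
]

#: the 36 states and union territories grouped into six regions, the
#: administrative frame the India preset emulates (NFHS-5 frame).
INDIA_STATES: tuple[str, ...] = (
    "Jammu & Kashmir", "Himachal Pradesh", "Punjab", "Chandigarh",
    "Uttarakhand", "Haryana", "NCT Of Delhi", "Rajasthan", "Ladakh",
    "Sikkim", "Arunachal Pradesh", "Nagaland", "Manipur", "Mizoram",
    "Tripura", "Meghalaya", "Assam",
    "Karnataka", "Lakshadweep", "Kerala", "Tamil Nadu", "Puducherry",
    "Andaman & Nicobar Islands", "Telangana", "Andhra Pradesh",
    "Bihar", "West Bengal", "Jharkhand", "Odisha",
    "Gujarat", "Dadra & Nagar Haveli", "Maharashtra", "Goa",
    "Chhattisgarh", "Madhya Pradesh", "Uttar Pradesh",
)

#: missing-value sentinel used in all delimited survey files
NA_SENTINEL = "NA"


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic survey generator.

    Parameters mirror the data-generating model: a grand intercept ``beta0``
    on the log-odds scale and three variance components (log-odds^2) for the
    cluster, district and state random intercepts. ``clusters_per_district``
    and ``births_per_cluster`` may be a single count or an inclusive
    ``(low, high)`` range sampled uniformly.
    """

    n_states: int = 30
    districts_per_state: int | Sequence[int] = 24
    clusters_per_district: int | tuple[int, int] = (20, 40)
    births_per_cluster: int | tuple[int, int] = (10, 40)
    beta0: float = -1.5
    sigma2_u: float = 0.30
    sigma2_v: float = 0.20
    sigma2_f: float = 0.15
    missing_rate: float = 0.15
    waves: Sequence[str] = ("NFHS-4", "NFHS-5")
    state_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta0", "sigma2_u", "sigma2_v", "sigma2_f", "missing_rate"):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ValueError(f"GeneratorConfig.{name} must be finite, got {val!r}")
        for name in ("sigma2_u", "sigma2_v", "sigma2_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"GeneratorConfig.{name} must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("GeneratorConfig.missing_rate must lie in [0, 1]")
        if self.n_states < 1:
            raise ValueError("GeneratorConfig.n_states must be >= 1")
        for name in ("districts_per_state", "clusters_per_district", "births_per_cluster"):
            lo, hi = _as_range(getattr(self, name)) if name != "districts_per_state" else (
                (min(_as_list(self.districts_per_state)), max(_as_list(self.districts_per_state)))
            )
            if lo < 1:
                raise ValueError(f"GeneratorConfig.{name} counts must be >= 1")
            if hi < lo:
                raise ValueError(f"GeneratorConfig.{name} range must be (low, high) with low <= high")
        if len(self.waves) < 1:
            raise ValueError("GeneratorConfig.waves must name at least one wave")
        if self.state_names is not None and len(self.state_names) != self.n_states:
            raise ValueError("GeneratorConfig.state_names length must equal n_states")

    def to_json(self) -> str:
        d = asdict(self)
        d["waves"] = list(self.waves)
        if self.state_names is not None:
            d["state_names"] = list(self.state_names)
        return json.dumps(d, indent=2)


def _as_range(x) -> tuple[int, int]:
    if isinstance(x, (tuple, list)):
        lo, hi = int(x[0]), int(x[1])
        return lo, hi
    return int(x), int(x)


def _as_list(x):
    if isinstance(x, (tuple, list)):
        return [int(v) for v in x]
    return [int(x)]


@dataclass
class ExclusionReport:
    """Counts of unit records before and after dropping missing outcomes."""

    per_wave: dict
    before: int
    after: int

    @property
    def excluded(self) -> int:
        return self.before - self.after

    @property
    def empty_result(self) -> bool:
        return self.after == 0


@dataclass
class GeneratedSurvey:
    """A synthetic survey plus its sidecar ground truth.

    ``data`` has exactly the microdata contract columns
    ``state_id,district_id,cluster_id,birth_id,wave,lbw`` with lbw a nullable
    integer (pd.NA when the birth weight is unrecorded). ``truth`` holds the
    realised random effects and cluster-level true probabilities per wave.
    """

    data: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def generate_survey(config: GeneratorConfig) -> GeneratedSurvey:
    """Draw a full multi-wave survey under the four-level logistic model.

    Per wave: state intercepts f_l ~ N(0, sigma2_f), district intercepts
    v_kl ~ N(0, sigma2_v), cluster intercepts u_jkl ~ N(0, sigma2_u), then
    each birth's LBW indicator ~ Bernoulli(invlogit(beta0 + u + v + f)).
    Finally each record's outcome is masked with probability
    ``missing_rate`` (MCAR). Identical config and seed give byte-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    if config.state_names is not None:
        state_names = [str(s) for s in config.state_names]
    else:
        state_names = [f"S{i + 1:02d}" for i in range(config.n_states)]

    dps = _as_list(config.districts_per_state)
    if len(dps) == 1:
        dps = dps * config.n_states
    elif len(dps) != config.n_states:
        raise ValueError("districts_per_state list must have one entry per state")

    frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    for wave in config.waves:
        frames_w, truth_w = _generate_wave(config, rng, str(wave), state_names, dps)
        frames.append(frames_w)
        truth_frames.append(truth_w)

    data = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return GeneratedSurvey(data=data, truth=truth, config=config)


def _generate_wave(config, rng, wave, state_names, dps):
    clo, chi = _as_range(config.clusters_per_district)
    blo, bhi = _as_range(config.births_per_cluster)

    district_ids: list[str] = []
    district_state: list[int] = []
    for s, nd in enumerate(dps):
        for d in range(nd):
            district_ids.append(f"{state_names[s]}::d{d + 1:03d}")
            district_state.append(s)
    district_state_arr = np.asarray(district_state)
    n_states = len(state_names)
    n_districts = len(district_ids)

    n_clusters_per_d = rng.integers(clo, chi + 1, size=n_districts)
    n_clusters = int(n_clusters_per_d.sum())
    cluster_district = np.repeat(np.arange(n_districts), n_clusters_per_d)
    # cluster ids unique within the wave (fresh PSUs are drawn per round)
    within = np.concatenate([np.arange(k) for k in n_clusters_per_d])
    cluster_ids = np.asarray(
        [f"{district_ids[d]}::{wave}::c{w + 1:03d}" for d, w in zip(cluster_district, within)]
    )

    f = rng.normal(0.0, math.sqrt(config.sigma2_f), size=n_states)
    v = rng.normal(0.0, math.sqrt(config.sigma2_v), size=n_districts)
    u = rng.normal(0.0, math.sqrt(config.sigma2_u), size=n_clusters)
    eta = config.beta0 + u + v[cluster_district] + f[district_state_arr[cluster_district]]
    p = expit(eta)

    n_births = rng.integers(blo, bhi + 1, size=n_clusters)
    total = int(n_births.sum())
    birth_cluster = np.repeat(np.arange(n_clusters), n_births)
    y = (rng.random(total) < p[birth_cluster]).astype("int64")
    lbw = pd.array(y, dtype="Int64")
    if config.missing_rate > 0:
        lbw[rng.random(total) < config.missing_rate] = pd.NA

    birth_within = np.concatenate([np.arange(k) for k in n_births])
    data = pd.DataFrame(
        {
            "state_id": np.asarray(state_names)[district_state_arr[cluster_district[birth_cluster]]],
            "district_id": np.asarray(district_ids)[cluster_district[birth_cluster]],
            "cluster_id": cluster_ids[birth_cluster],
            "birth_id": [f"b{i + 1:03d}" for i in birth_within],
            "wave": wave,
            "lbw": lbw,
        }
    )
    truth = pd.DataFrame(
        {
            "wave": wave,
            "cluster_id": cluster_ids,
            "district_id": np.asarray(district_ids)[cluster_district],
            "state_id": np.asarray(state_names)[district_state_arr[cluster_district]],
            "u": u,
            "v": v[cluster_district],
            "f": f[district_state_arr[cluster_district]],
            "eta": eta,
            "p_true": p,
            "n_births": n_births,
        }
    )
    return data, truth


def apply_exclusions(data: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop records with missing LBW outcome (complete-case analysis).

    Returns the retained rows and a per-wave before/after count report. An
    empty result is allowed and flagged on the report.
    """
    missing = data["lbw"].isna()
    kept = data.loc[~missing].reset_index(drop=True)
    per_wave = {}
    for wave, grp in data.groupby("wave", sort=True):
        per_wave[str(wave)] = {
            "before": int(len(grp)),
            "after": int(grp["lbw"].notna().sum()),
        }
    report = ExclusionReport(per_wave=per_wave, before=int(len(data)), after=int(len(kept)))
    return kept, report


def india_preset(**overrides) -> GeneratorConfig:
    """Generator configured to mimic the Indian two-round survey frame.

    36 states/UTs with their real names (so the packaged state-to-region map
    applies), 20 districts each for 720 districts in total, two waves.
    """
    params = dict(
        n_states=len(INDIA_STATES),
        state_names=INDIA_STATES,
        districts_per_state=20,
        waves=("NFHS-4", "NFHS-5"),
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def sample_adp_districts(district_ids: Sequence[str], n_adp: int = 117, seed: int = 0) -> list[str]:
    """Pick a random subset of districts to flag as Aspirational Districts.

    The real programme designated 117 of 720 districts; synthetic mode
    reproduces that rate by simple random sampling without replacement.
    """
    ids = sorted(set(map(str, district_ids)))
    if n_adp > len(ids):
        raise ValueError(f"cannot flag {n_adp} ADP districts among {len(ids)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=n_adp, replace=False)
    return sorted(ids[i] for i in picked)


def write_survey(survey: GeneratedSurvey, path: str | Path) -> None:
    """Write the survey CSV plus the ``*.truth.csv`` sidecar and config echo.

    The survey file has exactly the six contract columns with ``NA`` as the
    missing sentinel; the truth never enters the survey file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    survey.data.to_csv(path, index=False, na_rep=NA_SENTINEL)
    survey.truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    path.with_suffix(".config.json").write_text(survey.config.to_json())


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV written under the microdata contract."""
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in ("state_id", "district_id", "cluster_id", "birth_id", "wave")},
        na_values=[NA_SENTINEL],
        keep_default_na=False,
    )
    df["lbw"] = df["lbw"].astype("Int64")
    return df
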