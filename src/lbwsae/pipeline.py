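"""End-to-end orchestration: exclusions -> per-wave fit -> cluster/district
estimates -> two-wave change analytics, with a machine-readable manifest.

Every stage consumes and produces the documented CSV/JSON contracts so the
stages are independently runnable and testable. All randomness flows from
one root seed: each stage derives its own 31-bit seed as
``blake2b(f"{root}:{stage}")``, so a stage can be re-run reproducibly in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .change import (
    band_table,
    compute_change,
    correlate,
    load_adp_districts,
    load_region_map,
    summarize_region,
)
from .hierfit import FitConfig, diagnose, fit_mcmc
from .sae import cluster_probabilities, district_prevalence
from .synth import (
    GeneratorConfig,
    apply_exclusions,
    generate_survey,
    read_survey,
    sample_adp_districts,
    write_survey,
)

__all__ = ["PipelineConfig", "PipelineError", "derive_seed", "run_pipeline"]


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage 31-bit seed derived from the root seed."""
    digest = hashlib.blake2b(f"{root_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``generator`` is set (simulate mode) or ``data_paths`` maps each
    wave label to a microdata CSV. ``region_map``/``adp_districts``/
    ``crosswalk`` default to the packaged fixtures (ADP assignment in
    simulate mode is drawn at the 117/720 rate when the packaged fixture
    does not cover the simulated districts).
    """

    out_dir: str | Path = "results/run"
    seed: int = 0
    generator: GeneratorConfig | None = None
    data_paths: dict = field(default_factory=dict)
    crosswalk_path: str | Path | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    use_packaged_fixtures: bool = True


def _load_crosswalk(path):
    cw = pd.read_csv(path, dtype="string")
    need = {"cluster_id", "district_id"}
    if not need <= set(cw.columns):
        raise PipelineError("predict", f"crosswalk lacks columns {sorted(need - set(cw.columns))}")
    return cw


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artefacts under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``). Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # --- stage: acquire data -------------------------------------------------
    truth = None
    if config.generator is not None:
        stage_seed = derive_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = stage_seed
        gen_cfg = config.generator
        gen_cfg = GeneratorConfig(**{**gen_cfg.__dict__, "seed": stage_seed})
        survey = generate_survey(gen_cfg)
        write_survey(survey, out / "survey.csv")
        data = survey.data
        truth = survey.truth
        manifest["stages"]["simulate"] = {"rows": int(len(data)), "config": json.loads(gen_cfg.to_json())}
    elif config.data_paths:
        frames = []
        for wave, path in config.data_paths.items():
            if not Path(path).exists():
                raise PipelineError("load", f"microdata path {path} for wave {wave!r} does not exist")
            df = read_survey(path)
            df["wave"] = str(wave)
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        manifest["stages"]["load"] = {"rows": int(len(data))}
    else:
        raise PipelineError("load", "neither a generator config nor data paths were given")

    # --- stage: exclusions ---------------------------------------------------
    data, report = apply_exclusions(data)
    manifest["stages"]["exclusions"] = {
        "before": report.before, "after": report.after, "per_wave": report.per_wave,
    }
    if report.empty_result:
        raise PipelineError("exclusions", "no records remain after dropping missing outcomes")

    waves = sorted(data["wave"].unique())
    crosswalk = _load_crosswalk(config.crosswalk_path) if config.crosswalk_path else None

    # --- stages: per-wave fit + prediction -----------------------------------
    district_frames = {}
    for wave in waves:
        stage = f"fit:{wave}"
        stage_seed = derive_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = stage_seed
        fit_cfg = FitConfig(**{**config.fit.__dict__, "seed": stage_seed})
        sub = data.loc[data["wave"] == wave]
        try:
            draws = fit_mcmc(sub, fit_cfg)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(stage, str(exc)) from exc
        diag = diagnose(draws) if draws.n_draws >= 2 else None
        draws.summary().to_csv(out / f"posterior_{_slug(wave)}.csv", index=False)
        manifest["stages"][stage] = {
            "n_draws": draws.n_draws,
            "acceptance": draws.meta["acceptance"],
            "diagnostics": diag.table.to_dict("records") if diag else None,
            "flags": diag.flags if diag else [],
        }

        try:
            clusters = cluster_probabilities(draws)
            wave_cw = None
            if crosswalk is not None:
                wave_cw = crosswalk
                if "wave" in crosswalk.columns:
                    wave_cw = crosswalk.loc[crosswalk["wave"] == wave].drop(columns=["wave"])
            districts = district_prevalence(clusters, wave_cw)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"predict:{wave}", str(exc)) from exc
        clusters.to_csv(out / f"clusters_{_slug(wave)}.csv", index=False)
        districts.to_csv(out / f"districts_{_slug(wave)}.csv", index=False)
        district_frames[wave] = districts
        manifest["stages"][f"predict:{wave}"] = {
            "n_clusters": int(len(clusters)), "n_districts": int(len(districts)),
        }

    # --- stage: change analytics --------------------------------------------
    region_map = load_region_map() if config.use_packaged_fixtures else None
    if len(waves) >= 2:
        first, second = waves[0], waves[-1]
        d1 = district_frames[first].drop(columns=["wave"])
        d2 = district_frames[second].drop(columns=["wave"])
        states = set(d1["state_id"]) | set(d2["state_id"])
        if region_map is not None and not states <= set(region_map["state"]):
            region_map = None  # generic (non-India) state names: skip regions
        adp = None
        if config.use_packaged_fixtures:
            packaged = set(load_adp_districts())
            if packaged <= set(d1["district_id"]) | set(d2["district_id"]):
                adp = sorted(packaged)
            else:
                adp_seed = derive_seed(config.seed, "adp")
                manifest["stage_seeds"]["adp"] = adp_seed
                ids = sorted(set(d1["district_id"]) & set(d2["district_id"]))
                n_adp = max(1, round(len(ids) * 117 / 720))
                adp = sample_adp_districts(ids, n_adp=n_adp, seed=adp_seed)

        try:
            records = compute_change(d1, d2, region_map=region_map, adp_districts=adp)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("change", str(exc)) from exc
        records.to_csv(out / "changes.csv", index=False)

        tables = [band_table(records, "all")]
        if region_map is not None:
            tables.append(band_table(records, "region"))
        if adp is not None:
            tables.append(band_table(records, "adp"))
        pd.concat(tables, ignore_index=True).to_csv(out / "band_table.csv", index=False)

        if region_map is not None:
            all_est = pd.concat(district_frames.values(), ignore_index=True)
            summarize_region(all_est, region_map).to_csv(out / "region_summary.csv", index=False)

        corr = {"n_districts": int(len(records))}
        if len(records) >= 3:
            r_levels, p_levels = correlate(
                records["prevalence_first_pct"], records["prevalence_second_pct"]
            )
            r_change, p_change = correlate(
                records["prevalence_first_pct"], records["change_pp"]
            )
            corr["prevalence_first_vs_second"] = {"r": r_levels, "p": p_levels}
            corr["prevalence_first_vs_change"] = {"r": r_change, "p": p_change}
        (out / "correlations.json").write_text(json.dumps(corr, indent=2))
        manifest["stages"]["change"] = {
            "n_districts": int(len(records)),
            "unmatched": len(records.attrs.get("unmatched", [])),
            "correlations": corr,
        }

    if truth is not None:
        manifest["stages"]["truth_sidecar"] = {"path": "survey.truth.csv"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def _slug(wave: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in str(wave)).strip("_").lower()
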