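"""Published NFHS district LBW summaries bundled for arithmetic validation.

The national analysis of the 2016 and 2021 NFHS rounds reports region-level
LBW prevalences and the counts of the 720 districts falling in each of the
seven change bands (nationally, by region, and for the 117 Aspirational
Districts). Those printed tables are bundled here as inputs so the change
arithmetic — percentage-point differences, band shares and the >3-point
aggregates — can be recomputed and checked without the access-controlled
microdata.
"""

from __future__ import annotations

import pandas as pd

from .change import band_percentages_from_counts, compute_change, _read_fixture

__all__ = [
    "load_region_prevalence",
    "load_band_counts",
    "region_change_table",
    "band_share_table",
]


def load_region_prevalence() -> pd.DataFrame:
    """Region-level LBW prevalence (%) per wave, as published."""
    return _read_fixture("nfhs_region_prevalence.csv")


def load_band_counts() -> pd.DataFrame:
    """Published district counts per change band, per group."""
    return _read_fixture("nfhs_band_counts.csv")


def region_change_table() -> pd.DataFrame:
    """Recompute the region change column from the published prevalences."""
    tab = load_region_prevalence()
    d16 = pd.DataFrame(
        {"district_id": tab["region"], "state_id": tab["region"],
         "prevalence_pct": tab["prevalence_2016_pct"]}
    )
    d21 = pd.DataFrame(
        {"district_id": tab["region"], "state_id": tab["region"],
         "prevalence_pct": tab["prevalence_2021_pct"]}
    )
    rec = compute_change(d16, d21)
    return rec.rename(columns={"district_id": "region"})[
        ["region", "prevalence_first_pct", "prevalence_second_pct", "change_pp", "band"]
    ]


def band_share_table() -> pd.DataFrame:
    """Recompute band percentage shares and aggregates from published counts."""
    counts = load_band_counts()
    rows = []
    for _, row in counts.iterrows():
        summ = band_percentages_from_counts([row[f"count_{i}"] for i in range(1, 8)])
        out = {"group": row["group"], "total": summ["total"]}
        for i in range(7):
            out[f"pct_{i + 1}"] = summ["pct"][i]
        out["reduction_gt3_pct"] = summ["reduction_gt3_pct"]
        out["increase_gt3_pct"] = summ["increase_gt3_pct"]
        rows.append(out)
    return pd.DataFrame(rows)
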