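"""Two-wave change analytics: percentage-point changes, seven-band
categorisation, regional/ADP stratified summaries, correlations, quadrants.

Conventions fixed here (and relied on by the published-table arithmetic):

* Prevalences are rounded to 2 decimal places (half away from zero) before
  differencing, so a change is itself an exact multiple of 0.01 and banding
  is done on integer hundredths — no floating-point edge cases.
* The seven change bands partition the rounded line; the bottom band is
  change <= -5.00, mirroring the "5.00 and above" top band.
* Band-table percentages are 2-dp-rounded shares of the group total; the
  "more than 3-point" reduction/increase aggregates are sums of the two
  extreme *rounded* band percentages on each side.
* Quartiles use linear interpolation; IQR = Q3 - Q1.
* Quadrant ties go to the lower side (a point exactly at both cutoffs is
  bottom-left).
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BAND_LABELS",
    "round2",
    "categorize_change",
    "compute_change",
    "band_percentages_from_counts",
    "band_table",
    "summarize_region",
    "correlate",
    "quadrant_classify",
    "load_region_map",
    "load_adp_districts",
    "REGIONS",
]

REGIONS = ("North", "North-East", "South", "East", "West", "Central")

#: ordered band labels; interval bounds in integer hundredths of a point
BAND_LABELS = (
    "less than -5.00",
    "-4.99 to -3.00",
    "-2.99 to -1.00",
    "-0.99 to 0.99",
    "1.00 to 2.99",
    "3.00 to 4.99",
    "5.00 and above",
)
_BAND_UPPER_CENTS = (-500, -300, -100, 99, 299, 499)  # inclusive upper bounds


def round2(x):
    """Round to 2 decimals, halves away from zero (as in printed tables)."""
    x = np.asarray(x, dtype=float)
    out = np.copysign(np.floor(np.abs(x) * 100.0 + 0.5), x) / 100.0
    return float(out) if out.ndim == 0 else out


def _cents(x) -> np.ndarray:
    """Integer hundredths of a 2-dp value (exact banding arithmetic)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) * 100.0 + 0.5), x).astype(np.int64)


def categorize_change(change_pp: float) -> str:
    """Band label for a percentage-point change (finite input required)."""
    if not np.isfinite(change_pp):
        raise ValueError(f"change must be finite, got {change_pp!r}")
    c = int(_cents(change_pp))
    for label, upper in zip(BAND_LABELS, _BAND_UPPER_CENTS):
        if c <= upper:
            return label
    return BAND_LABELS[-1]


def compute_change(
    d_first: pd.DataFrame,
    d_second: pd.DataFrame,
    region_map: pd.DataFrame | None = None,
    adp_districts=None,
) -> pd.DataFrame:
    """Per-district change records between two waves of district estimates.

    ``d_first`` is the earlier wave (2016 role), ``d_second`` the later
    (2021 role); change = round2(second) - round2(first), in percentage
    points. Districts present in only one wave are excluded (and reported
    via ``.attrs['unmatched']``). Region and ADP flags are joined from the
    given fixtures when supplied.
    """
    for name, d in (("first", d_first), ("second", d_second)):
        if d["district_id"].duplicated().any():
            bad = d.loc[d["district_id"].duplicated(), "district_id"].iloc[0]
            raise ValueError(f"duplicate district {bad!r} in {name}-wave estimates")

    a = d_first.set_index("district_id")
    b = d_second.set_index("district_id")
    common = a.index.intersection(b.index)
    unmatched = sorted(set(a.index).symmetric_difference(b.index))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} district(s) present in only one wave were excluded",
            RuntimeWarning,
            stacklevel=2,
        )

    p1 = round2(a.loc[common, "prevalence_pct"].to_numpy())
    p2 = round2(b.loc[common, "prevalence_pct"].to_numpy())
    change = (_cents(p2) - _cents(p1)) / 100.0
    rec = pd.DataFrame(
        {
            "district_id": np.asarray(common),
            "state_id": a.loc[common, "state_id"].to_numpy(),
            "prevalence_first_pct": p1,
            "prevalence_second_pct": p2,
            "change_pp": change,
            "band": [categorize_change(c) for c in change],
        }
    )
    if region_map is not None:
        rmap = region_map.set_index("state")["region"]
        missing = set(rec["state_id"]) - set(rmap.index)
        if missing:
            raise KeyError(f"state {sorted(missing)[0]!r} absent from the region map")
        rec["region"] = rec["state_id"].map(rmap).to_numpy()
    if adp_districts is not None:
        adp = set(map(str, adp_districts))
        rec["adp_flag"] = rec["district_id"].astype(str).isin(adp).to_numpy()
    rec.attrs["unmatched"] = unmatched
    return rec


def band_percentages_from_counts(counts) -> dict:
    """Band shares (2-dp percent) and >3-point aggregates from band counts.

    ``counts`` is the 7-vector of district counts per band, in band order.
    The reduction/increase aggregates sum the two extreme rounded
    percentages on each side, matching how published tables combine them.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (7,):
        raise ValueError("expected exactly 7 band counts")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty group: no districts to band")
    pct = round2(100.0 * counts / total)
    return {
        "counts": counts.tolist(),
        "total": total,
        "pct": pct.tolist(),
        "reduction_gt3_pct": float(round2(pct[0] + pct[1])),
        "increase_gt3_pct": float(round2(pct[5] + pct[6])),
    }


def band_table(records: pd.DataFrame, group_by: str = "all") -> pd.DataFrame:
    """Counts and percentage shares per band, overall or stratified.

    ``group_by`` is ``"all"`` (single national row), ``"region"`` or
    ``"adp"``. Output has one row per group with ``count_<i>`` /
    ``pct_<i>`` columns in band order plus the two >3-point aggregates.
    """
    if group_by == "all":
        groups = [("India", records)]
    elif group_by == "region":
        groups = [(r, g) for r, g in records.groupby("region", sort=False)]
        order = {r: i for i, r in enumerate(REGIONS)}
        groups.sort(key=lambda kv: order.get(kv[0], 99))
    elif group_by == "adp":
        groups = [
            ("ADP" if flag else "non-ADP", g)
            for flag, g in records.groupby("adp_flag", sort=True)
        ]
        groups.sort(key=lambda kv: kv[0] != "ADP")
    else:
        raise ValueError(f"group_by must be 'all', 'region' or 'adp', got {group_by!r}")

    rows = []
    for name, grp in groups:
        counts = grp["band"].value_counts().reindex(BAND_LABELS, fill_value=0).to_numpy()
        summ = band_percentages_from_counts(counts)
        row = {"group": name, "total": summ["total"]}
        for i in range(7):
            row[f"count_{i + 1}"] = summ["counts"][i]
            row[f"pct_{i + 1}"] = summ["pct"][i]
        row["reduction_gt3_pct"] = summ["reduction_gt3_pct"]
        row["increase_gt3_pct"] = summ["increase_gt3_pct"]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_region(
    estimates: pd.DataFrame,
    region_map: pd.DataFrame,
    overall_label: str = "India",
) -> pd.DataFrame:
    """Median, quartiles and IQR of district prevalences per region per wave.

    Quartiles use linear interpolation between order statistics. An overall
    row across all districts is included under ``overall_label``.
    """
    rmap = region_map.set_index("state")["region"]
    df = estimates.copy()
    df["region"] = df["state_id"].map(rmap)
    if df["region"].isna().any():
        bad = df.loc[df["region"].isna(), "state_id"].iloc[0]
        raise KeyError(f"state {bad!r} absent from the region map")

    rows = []
    for (wave, region), grp in df.groupby(["wave", "region"], sort=True):
        rows.append(_quartile_row(region, wave, grp["prevalence_pct"]))
    for wave, grp in df.groupby("wave", sort=True):
        rows.append(_quartile_row(overall_label, wave, grp["prevalence_pct"]))
    return pd.DataFrame(rows)


def _quartile_row(region, wave, values):
    x = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return dict(
        region=region, wave=wave, n_districts=int(x.size),
        median=float(med), q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("need >= 3 paired finite values")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def quadrant_classify(x, y, cutoffs: tuple[float, float] | None = None) -> list[str]:
    """Label points bottom-left/bottom-right/top-left/top-right.

    Cutoffs default to the medians of x and y. Ties sit on the lower side:
    x <= cutoff is "left", y <= cutoff is "bottom".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = cutoffs if cutoffs is not None else (float(np.median(x)), float(np.median(y)))
    labels = []
    for xi, yi in zip(x, y):
        vert = "bottom" if yi <= cy else "top"
        horiz = "left" if xi <= cx else "right"
        labels.append(f"{vert}-{horiz}")
    return labels


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("lbwsae.fixtures").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_region_map() -> pd.DataFrame:
    """Packaged state/UT -> six-region assignment (columns state, region)."""
    return _read_fixture("regions.csv")


def load_adp_districts() -> list[str]:
    """Packaged Aspirational District Programme membership (117 slots).

    The shipped file is a synthetic stand-in keyed to the India-preset
    district ids; replace it with real programme districts for real data.
    """
    return _read_fixture("adp_districts.synthetic.csv")["district_id"].astype(str).tolist()
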