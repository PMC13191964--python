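"""Schema and hierarchy validation of survey microdata files."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synth import NA_SENTINEL

__all__ = ["ValidationError", "ValidationReport", "validate_microdata"]

REQUIRED_COLUMNS = ("state_id", "district_id", "cluster_id", "birth_id", "wave", "lbw")


@dataclass
class ValidationReport:
    """Structured list of schema violations, each with a row number."""

    path: str
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, row: int | None, message: str) -> None:
        self.violations.append({"row": row, "message": message})

    def __str__(self) -> str:
        lines = [f"validation of {self.path}: {len(self.violations)} violation(s)"]
        for v in self.violations[:50]:
            loc = f"row {v['row']}" if v["row"] is not None else "file"
            lines.append(f"  {loc}: {v['message']}")
        return "\n".join(lines)


class ValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        super().__init__(str(report))
        self.report = report


def validate_microdata(path: str | Path) -> pd.DataFrame:
    """Load a microdata CSV, enforcing the survey contract.

    Checks: required columns present; lbw in {0, 1, NA}; no cluster under
    two districts within a wave; no district under two states. Raises
    ``ValidationError`` carrying a row-numbered report on any violation.
    Row numbers are 1-based file lines (header is line 1).
    """
    path = Path(path)
    report = ValidationReport(path=str(path))
    df = pd.read_csv(path, dtype="string", na_values=[NA_SENTINEL], keep_default_na=False)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        report.add(None, f"missing required column(s): {missing}")
        raise ValidationError(report)

    bad_lbw = ~(df["lbw"].isna() | df["lbw"].isin(["0", "1"]))
    for idx in df.index[bad_lbw]:
        report.add(int(idx) + 2, f"lbw value {df.at[idx, 'lbw']!r} not in {{0, 1, NA}}")

    for col in ("state_id", "district_id", "cluster_id", "birth_id", "wave"):
        blank = df[col].isna() | (df[col].str.len() == 0)
        for idx in df.index[blank][:20]:
            report.add(int(idx) + 2, f"empty {col}")

    # hierarchy consistency within each wave
    for wave, grp in df.groupby("wave", sort=True):
        cd = grp.groupby("cluster_id")["district_id"].nunique()
        for cluster in cd.index[cd > 1]:
            first = grp.index[grp["cluster_id"] == cluster][0]
            report.add(int(first) + 2,
                       f"cluster {cluster!r} appears under multiple districts in wave {wave!r}")
        ds = grp.groupby("district_id")["state_id"].nunique()
        for district in ds.index[ds > 1]:
            first = grp.index[grp["district_id"] == district][0]
            report.add(int(first) + 2,
                       f"district {district!r} appears under multiple states in wave {wave!r}")

    if not report.ok:
        raise ValidationError(report)

    out = df.copy()
    out["lbw"] = out["lbw"].astype("Int64")
    return out
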