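"""Study-table reading and report writing.

Comparison tables follow a fixed column order per region: mean and SD over
all scans, CV%RMS, OA central value (mean, or median for non-normal rows)
and SD, normal central value and SD, absolute and percent difference, 95%
CI bounds, p-value and Cohen's d.  The same layout is used for the bundled
reference tables from the in vivo study this pipeline reimplements
(minimum principal stress, minimum principal strain and compartmental
structural stiffness across the 17 proximal-tibia regions), for tables the
pipeline itself emits, and for round-tripping either through CSV.

Rounding in reports mirrors the reference format: 2 decimals for stress
(MPa), integers for microstrain and N/mm, 1 decimal for percents and CV.
No multiple-testing correction is applied across regions (noted in the
report output).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import ComparisonRow

__all__ = [
    "COMPARISON_COLUMNS",
    "load_reference_table",
    "read_comparison_csv",
    "write_comparison_csv",
    "comparison_dataframe",
    "summarize_cv",
    "to_markdown",
]

COMPARISON_COLUMNS = [
    "region",
    "non_normal",
    "all_mean",
    "all_sd",
    "cv_rms",
    "oa_central",
    "oa_sd",
    "normal_central",
    "normal_sd",
    "difference_absolute",
    "difference_percent",
    "ci_low",
    "ci_high",
    "p_value",
    "cohens_d",
]

REFERENCE_TABLES = ("min_principal_stress", "min_principal_strain", "structural_stiffness")


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one bundled reference comparison table by metric name."""
    if name not in REFERENCE_TABLES:
        raise ValueError(f"unknown reference table {name!r}; options: {REFERENCE_TABLES}")
    ref = resources.files("tibiamech").joinpath(f"data/reference_study/{name}.csv")
    with resources.as_file(ref) as path:
        return read_comparison_csv(path)


def read_comparison_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COMPARISON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"comparison table missing columns: {missing}")
    return df[COMPARISON_COLUMNS]


def write_comparison_csv(df: pd.DataFrame, path) -> None:
    df[COMPARISON_COLUMNS].to_csv(path, index=False)


def comparison_dataframe(rows: list[ComparisonRow], all_mean=None) -> pd.DataFrame:
    """Assemble ComparisonRow results into the standard table layout."""
    recs = []
    for r in rows:
        recs.append(
            {
                "region": r.region,
                "non_normal": int(r.distribution_flag == "non_normal"),
                "all_mean": r.mean_all,
                "all_sd": r.sd_all,
                "cv_rms": np.nan,  # filled by the caller from the precision table
                "oa_central": r.central_oa,
                "oa_sd": r.sd_oa,
                "normal_central": r.central_normal,
                "normal_sd": r.sd_normal,
                "difference_absolute": r.difference_absolute,
                "difference_percent": r.difference_percent,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "cohens_d": r.cohens_d,
            }
        )
    return pd.DataFrame.from_records(recs, columns=COMPARISON_COLUMNS)


def summarize_cv(df: pd.DataFrame) -> dict:
    """Arithmetic mean / min / max of a table's CV%RMS column."""
    cv = df["cv_rms"].astype(float)
    return {
        "mean": float(cv.mean()),
        "min": float(cv.min()),
        "max": float(cv.max()),
        "n": int(cv.notna().sum()),
    }


_ROUNDING = {
    "stress": {"value": 2, "percent": 1},
    "strain": {"value": 0, "percent": 1},
    "stiffness": {"value": 0, "percent": 1},
}


def to_markdown(df: pd.DataFrame, kind: str = "stress") -> str:
    """Markdown rendering with the reference rounding conventions."""
    fmt = _ROUNDING.get(kind, _ROUNDING["stress"])
    out = df.copy()
    value_cols = [
        "all_mean",
        "all_sd",
        "oa_central",
        "oa_sd",
        "normal_central",
        "normal_sd",
        "difference_absolute",
        "ci_low",
        "ci_high",
    ]
    for c in value_cols:
        out[c] = out[c].astype(float).round(fmt["value"])
        if fmt["value"] == 0:
            out[c] = out[c].astype("Int64")
    out["difference_percent"] = out["difference_percent"].astype(float).round(fmt["percent"])
    out["cv_rms"] = out["cv_rms"].astype(float).round(1)
    out["p_value"] = out["p_value"].astype(float).round(3)
    out["cohens_d"] = out["cohens_d"].astype(float).round(2)
    lines = ["| " + " | ".join(COMPARISON_COLUMNS) + " |",
             "|" + "---|" * len(COMPARISON_COLUMNS)]
    for _, row in out.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in COMPARISON_COLUMNS) + " |")
    lines.append("")
    lines.append("No multiple-testing correction is applied across regions.")
    return "\n".join(lines)
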