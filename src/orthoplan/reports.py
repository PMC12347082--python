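"""Render the three cohort report tables (CSV + full-precision JSON).

The layouts mirror the clinical convention for planning-accuracy
studies: per segment, (1) mean difference / SEM / top-10% magnitude /
95% CI / one-sample p per parameter; (2) out-of-range percentages at
the clinical tolerances with rotation/translation mean rows; (3)
unpaired subgroup contrasts (mean difference, 95% CI, p) for each
treatment covariate.  CSV cells are rendered at two decimals with
p-values below 0.001 printed as "<0.001"; the JSON twin keeps full
precision.  No multiple-testing correction is applied; the JSON records
the number of tests performed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .stats import (
    COVARIATES,
    StatsInputError,
    format_p,
    one_sample_summary,
    subgroup_test,
    tolerance_report,
)
from .triangles import PARAMETERS, SEGMENTS

__all__ = ["summary_report", "subgroup_report", "write_reports"]


def summary_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-(segment, parameter) one-sample summary table."""
    rows = []
    for segment in SEGMENTS:
        seg = cohort[cohort["segment"] == segment]
        for p in PARAMETERS:
            r = one_sample_summary(seg[p])
            rows.append({"segment": segment, "parameter": p, **r.as_dict()})
    return pd.DataFrame(rows)


def subgroup_report(cohort: pd.DataFrame, covariates=COVARIATES, welch: bool = True) -> pd.DataFrame:
    """Unpaired contrasts of every parameter per covariate and segment."""
    rows = []
    for cov in covariates:
        for segment in SEGMENTS:
            for p in PARAMETERS:
                r = subgroup_test(cohort, cov, p, segment, welch=welch)
                rows.append({
                    "covariate": cov, "segment": segment, "parameter": p,
                    **r.as_dict(),
                })
    return pd.DataFrame(rows)


def _render_2dp(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            if c == "p_value":
                out[c] = out[c].map(format_p)
            else:
                out[c] = out[c].map(lambda v: f"{v:.2f}")
    return out


def write_reports(
    cohort: pd.DataFrame,
    out_dir: str | Path,
    rot_tol: float = 4.0,
    trans_tol: float = 2.0,
    welch: bool = True,
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Write the three report CSVs plus a machine-readable JSON.

    Returns the mapping of report name to written path.  The subgroup
    report is skipped with a warning entry in the JSON when a covariate
    does not split the cohort into groups of at least two.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = summary_report(cohort)
    summary_out = _render_2dp(summary)
    summary_out["significant"] = summary["p_value"] < alpha
    paths["summary"] = out_dir / "report_summary.csv"
    summary_out.to_csv(paths["summary"], index=False, lineterminator="\n")

    tol = tolerance_report(cohort, rot_tol=rot_tol, trans_tol=trans_tol)
    paths["tolerance"] = out_dir / "report_tolerance.csv"
    tol.round(2).to_csv(paths["tolerance"], index_label="parameter", lineterminator="\n")

    payload = {
        "alpha": alpha,
        "rot_tol_deg": rot_tol,
        "trans_tol_mm": trans_tol,
        "welch": welch,
        "summary": summary.to_dict(orient="records"),
        "tolerance": {c: tol[c].to_dict() for c in tol.columns},
        "n_tests": len(summary),
        "warnings": [],
    }

    try:
        sub = subgroup_report(cohort, welch=welch)
        sub_out = _render_2dp(sub)
        sub_out["significant"] = sub["p_value"] < alpha
        paths["subgroups"] = out_dir / "report_subgroups.csv"
        sub_out.to_csv(paths["subgroups"], index=False, lineterminator="\n")
        payload["subgroups"] = sub.to_dict(orient="records")
        payload["n_tests"] += len(sub)
    except StatsInputError as exc:
        payload["warnings"].append(f"subgroup report skipped: {exc}")

    paths["json"] = out_dir / "report.json"
    paths["json"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return paths
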