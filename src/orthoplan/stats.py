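"""Cohort statistics for per-segment plan differences.

One row of the cohort table is one (patient, segment) pair carrying the
six clinical metrics plus the treatment covariates.  The layer computes,
per segment and parameter:

* a one-sample t-test of the cohort mean difference against zero, with
  SEM and 95% CI (df = n − 1),
* the "top-10%" value — the 90th empirical percentile of the absolute
  differences (10% of observations are larger in magnitude),
* the out-of-range percentage — the share of patients whose absolute
  difference strictly exceeds the clinical tolerance (default 4° for
  rotations, 2 mm for translations),
* unpaired two-sample contrasts between covariate subgroups (SARME,
  extraction site), Welch by default.

No multiple-testing correction is applied; reports annotate the number
of tests performed instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .triangles import (
    PARAMETERS,
    ROTATION_PARAMETERS,
    SEGMENTS,
    TRANSLATION_PARAMETERS,
    ClinicalMetrics,
)

__all__ = [
    "COVARIATES",
    "StatResult",
    "SubgroupResult",
    "one_sample_summary",
    "ci_from_summary",
    "top10_value",
    "out_of_range_percent",
    "tolerance_report",
    "subgroup_test",
    "cohort_table",
]

COVARIATES = ("sarme", "extraction_maxilla", "extraction_mandible")

#: Row order of the tolerance report, matching the published table layout.
TOLERANCE_ROWS = (
    "pitch", "roll", "yaw", "mean_rotations",
    "trans_lr", "trans_ap", "trans_ud", "mean_translations",
)


class StatsInputError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class StatResult:
    """One-sample summary of per-patient differences for one parameter."""

    mean: float
    sem: float
    top10_value: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    degenerate: bool = False  # zero sample variance; t undefined

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "sem": self.sem, "top10_value": self.top10_value,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n": self.n,
        }


@dataclass(frozen=True)
class SubgroupResult:
    """Unpaired contrast of one parameter between covariate subgroups."""

    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_group: int
    n_rest: int

    def as_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_value,
            "n_group": self.n_group, "n_rest": self.n_rest,
        }


def _clean_values(values, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_n:
        raise StatsInputError(f"need at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise StatsInputError("values contain non-finite entries")
    return arr


def top10_value(values) -> float:
    """90th empirical percentile of the absolute differences.

    Linear interpolation between order statistics (numpy's default
    ``linear`` quantile method), so exactly 10% of the empirical mass
    lies above the returned magnitude.
    """
    arr = _clean_values(values, min_n=1)
    return float(np.percentile(np.abs(arr), 90.0, method="linear"))


def ci_from_summary(mean: float, sem: float, n: int) -> tuple[float, float]:
    """Two-sided 95% CI from a mean and SEM: ``mean ± t(0.975, n−1)·sem``."""
    if sem < 0:
        raise StatsInputError("sem must be non-negative")
    if n < 2:
        raise StatsInputError("need n >= 2 for a confidence interval")
    half = sps.t.ppf(0.975, n - 1) * sem
    return (mean - half, mean + half)


def p_from_summary(mean: float, sem: float, n: int) -> float:
    """Two-sided one-sample t-test p-value against 0 from mean and SEM."""
    if sem <= 0:
        raise StatsInputError("sem must be positive for a t-test")
    t = mean / sem
    return float(2.0 * sps.t.sf(abs(t), n - 1))


def one_sample_summary(values) -> StatResult:
    """Full one-sample summary of per-patient differences.

    Mean, SEM = sd/√n, two-sided t-test against 0 with df = n−1, 95% CI
    and the top-10% magnitude.  A zero-variance sample has no defined t
    statistic: the result is flagged ``degenerate`` with p reported as
    the limit (0 for a nonzero mean, 1 otherwise).
    """
    arr = _clean_values(values, min_n=2)
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    sem = sd / np.sqrt(n)
    top10 = top10_value(arr)
    if sem == 0.0:
        p = 0.0 if mean != 0.0 else 1.0
        return StatResult(mean, 0.0, top10, mean, mean, p, n, degenerate=True)
    ci_low, ci_high = ci_from_summary(mean, sem, n)
    t, p = sps.ttest_1samp(arr, 0.0)
    return StatResult(mean, sem, top10, ci_low, ci_high, float(p), n)


def out_of_range_percent(values, tolerance: float) -> float:
    """Percentage of values whose magnitude strictly exceeds the tolerance.

    The boundary is not counted: a difference exactly at the tolerance
    is within range.
    """
    if tolerance <= 0:
        raise StatsInputError("tolerance must be positive")
    arr = _clean_values(values, min_n=1)
    return float(100.0 * np.count_nonzero(np.abs(arr) > tolerance) / arr.size)


def cohort_table(
    metrics: list[ClinicalMetrics],
    covariates: pd.DataFrame | dict | None = None,
) -> pd.DataFrame:
    """Assemble (patient, segment) metric rows into the cohort table.

    ``covariates`` maps patient_id → the three boolean treatment flags
    (a DataFrame indexed by patient_id or a dict of dicts); missing
    covariates default to False.
    """
    rows = []
    for m in metrics:
        row = {"patient_id": m.patient_id, "segment": m.segment, **m.as_dict()}
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.duplicated(["patient_id", "segment"]).any():
        raise StatsInputError("duplicate (patient, segment) rows in cohort")
    if covariates is None:
        cov = pd.DataFrame(index=df["patient_id"].unique())
    elif isinstance(covariates, dict):
        cov = pd.DataFrame.from_dict(covariates, orient="index")
    else:
        cov = covariates.copy()
    for c in COVARIATES:
        if c not in cov.columns:
            cov[c] = False
    df = df.merge(
        cov[list(COVARIATES)].rename_axis("patient_id").reset_index(),
        on="patient_id", how="left",
    )
    df[list(COVARIATES)] = df[list(COVARIATES)].fillna(False).astype(bool)
    return df[["patient_id", "segment", *PARAMETERS, *COVARIATES]]


def tolerance_report(
    cohort: pd.DataFrame,
    rot_tol: float = 4.0,
    trans_tol: float = 2.0,
) -> pd.DataFrame:
    """Out-of-range percentages per segment with rotation/translation means.

    Returns a DataFrame (rows = parameters plus ``mean_rotations`` /
    ``mean_translations``, columns = segments).  Each mean row is the
    arithmetic mean of its three parameter percentages.
    """
    if cohort.empty:
        raise StatsInputError("cohort table is empty")
    out: dict[str, dict[str, float]] = {}
    for segment in SEGMENTS:
        seg = cohort[cohort["segment"] == segment]
        col: dict[str, float] = {}
        for p in ROTATION_PARAMETERS:
            col[p] = out_of_range_percent(seg[p], rot_tol)
        for p in TRANSLATION_PARAMETERS:
            col[p] = out_of_range_percent(seg[p], trans_tol)
        col["mean_rotations"] = float(np.mean([col[p] for p in ROTATION_PARAMETERS]))
        col["mean_translations"] = float(np.mean([col[p] for p in TRANSLATION_PARAMETERS]))
        out[segment] = col
    report = pd.DataFrame(out).loc[list(TOLERANCE_ROWS), list(SEGMENTS)]
    return report


def subgroup_test(
    cohort: pd.DataFrame,
    covariate: str,
    parameter: str,
    segment: str,
    welch: bool = True,
) -> SubgroupResult:
    """Unpaired t contrast of one parameter between covariate subgroups.

    ``mean_diff`` is group-with-effect minus group-without.  Welch's
    unequal-variance test (with Welch–Satterthwaite df for the CI) is
    the default; ``welch=False`` selects the pooled-variance Student
    test.
    """
    if covariate not in COVARIATES:
        raise StatsInputError(f"unknown covariate {covariate!r}; expected one of {COVARIATES}")
    if parameter not in PARAMETERS:
        raise StatsInputError(f"unknown parameter {parameter!r}")
    seg = cohort[cohort["segment"] == segment]
    flag = seg[covariate].astype(bool)
    a = seg.loc[flag, parameter].to_numpy(dtype=float)
    b = seg.loc[~flag, parameter].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsInputError(
            f"covariate {covariate!r} splits segment {segment!r} into groups of "
            f"{a.size} and {b.size}; need at least 2 in each"
        )
    mean_diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        _, p = sps.ttest_ind(a, b, equal_var=False)
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1 / na + 1 / nb)
        df = na + nb - 2
        _, p = sps.ttest_ind(a, b, equal_var=True)
    half = sps.t.ppf(0.975, df) * np.sqrt(se2)
    return SubgroupResult(
        mean_diff=mean_diff,
        ci_low=mean_diff - half,
        ci_high=mean_diff + half,
        p_value=float(p),
        n_group=int(na),
        n_rest=int(nb),
    )


def format_p(p: float, threshold: float = 0.001) -> str:
    """Render a p-value the way the clinical tables print it."""
    return f"<{threshold}" if p < threshold else f"{p:.3f}"
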