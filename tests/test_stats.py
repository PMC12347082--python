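"""One-sample summaries, tolerance analysis and subgroup contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from orthoplan.stats import (
    StatsInputError,
    ci_from_summary,
    cohort_table,
    format_p,
    one_sample_summary,
    out_of_range_percent,
    subgroup_test,
    tolerance_report,
    top10_value,
)
from orthoplan.triangles import PARAMETERS, SEGMENTS, ClinicalMetrics


def make_cohort(values_by_segment, covariates=None):
    """Cohort where every parameter of a segment carries the same values."""
    metrics = []
    n = len(next(iter(values_by_segment.values())))
    for seg in SEGMENTS:
        vals = values_by_segment.get(seg, np.zeros(n))
        for i, v in enumerate(vals):
            metrics.append(ClinicalMetrics(*([float(v)] * 6), segment=seg,
                                           patient_id=f"p{i}"))
    return cohort_table(metrics, covariates)


class TestOneSampleSummary:
    def test_symmetric_values_mean_zero_p_one(self):
        r = one_sample_summary([-1.0, 1.0])
        assert r.mean == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_oracle(self, rng):
        """t statistic, p and CI match the textbook formulas computed here
        from first principles."""
        x = rng.normal(0.4, 1.3, size=26)
        r = one_sample_summary(x)
        n = x.size
        mean = x.sum() / n
        sd = np.sqrt(((x - mean) ** 2).sum() / (n - 1))
        sem = sd / np.sqrt(n)
        t = mean / sem
        p = 2 * (1 - sps.t.cdf(abs(t), n - 1))
        assert r.mean == pytest.approx(mean, abs=1e-12)
        assert r.sem == pytest.approx(sem, abs=1e-12)
        assert r.p_value == pytest.approx(p, abs=1e-10)
        assert r.ci_low == pytest.approx(mean - sps.t.ppf(0.975, 25) * sem, abs=1e-10)
        assert r.ci_low <= r.mean <= r.ci_high

    def test_zero_variance_flagged(self):
        r = one_sample_summary([2.0, 2.0, 2.0])
        assert r.degenerate
        assert r.p_value == 0.0
        r0 = one_sample_summary([0.0, 0.0])
        assert r0.degenerate and r0.p_value == 1.0

    def test_input_contract(self):
        with pytest.raises(StatsInputError):
            one_sample_summary([1.0])
        with pytest.raises(StatsInputError):
            one_sample_summary([1.0, np.nan])


class TestCiFromSummary:
    def test_zero_sem_collapses(self):
        assert ci_from_summary(5.0, 0.0, 26) == (5.0, 5.0)

    def test_t_quantile_oracle(self):
        lo, hi = ci_from_summary(0.0, 1.0, 26)
        # Student t 97.5% quantile at 25 df
        assert hi == pytest.approx(2.059539, abs=1e-6)
        assert lo == -hi

    def test_width_monotone_in_sem_and_n(self):
        w = lambda sem, n: np.diff(ci_from_summary(0.0, sem, n))[0]
        assert w(2.0, 26) > w(1.0, 26)
        assert w(1.0, 10) > w(1.0, 100)


class TestTop10Value:
    def test_constant_and_single(self):
        assert top10_value([-3.0, -3.0, 3.0]) == 3.0
        assert top10_value([-7.0]) == 7.0

    def test_sort_and_interpolate_oracle(self):
        values = [v for k in range(1, 14) for v in (k, -k)]  # ±1..±13
        # 90th percentile of |values| = {1,1,...,13,13} by linear
        # interpolation between order statistics: h = 0.9*(26-1)+1 = 23.5
        # -> halfway between the 23rd (12) and 24th (12) order statistic
        srt = np.sort(np.abs(values))
        h = 0.9 * (len(values) - 1)
        expected = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
        assert top10_value(values) == pytest.approx(expected, abs=1e-12)
        assert top10_value(values) == pytest.approx(12.0, abs=1e-12)


class TestOutOfRange:
    def test_examples_and_boundary(self):
        assert out_of_range_percent([0.0, 0.0, 0.0], 4.0) == 0.0
        assert out_of_range_percent([1.0, 3.0, 5.0], 4.0) == pytest.approx(100 / 3)
        # exactly at tolerance is within range (strict >)
        assert out_of_range_percent([4.0, -4.0], 4.0) == 0.0

    def test_monotone_non_increasing_in_tolerance(self, rng):
        x = rng.normal(0, 3, size=50)
        tols = [0.5, 1.0, 2.0, 4.0, 8.0]
        percents = [out_of_range_percent(x, t) for t in tols]
        assert all(a >= b for a, b in zip(percents, percents[1:]))


class TestToleranceReport:
    def test_mean_rows_are_parameter_means(self, rng):
        cohort = make_cohort({seg: rng.normal(0, 3, 12) for seg in SEGMENTS})
        rep = tolerance_report(cohort)
        for seg in SEGMENTS:
            np.testing.assert_allclose(
                rep.loc["mean_rotations", seg],
                np.mean([rep.loc[p, seg] for p in ("pitch", "roll", "yaw")]),
            )
            np.testing.assert_allclose(
                rep.loc["mean_translations", seg],
                np.mean([rep.loc[p, seg] for p in ("trans_lr", "trans_ap", "trans_ud")]),
            )

    def test_all_zero_cohort(self):
        cohort = make_cohort({seg: np.zeros(5) for seg in SEGMENTS})
        rep = tolerance_report(cohort)
        assert (rep.to_numpy() == 0.0).all()


class TestSubgroupTest:
    @staticmethod
    def covariates(n, flags):
        return pd.DataFrame(
            {"sarme": flags}, index=[f"p{i}" for i in range(n)]
        )

    def test_identical_groups(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        cov = self.covariates(6, [True] * 3 + [False] * 3)
        cohort = make_cohort({seg: vals for seg in SEGMENTS}, cov)
        r = subgroup_test(cohort, "sarme", "pitch", "dental_maxilla")
        assert r.mean_diff == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_welch_closed_form_oracle(self):
        a = np.array([3.1, 2.4, 4.0, 3.3, 2.8])
        b = np.array([1.0, 1.9, 0.4, 1.5])
        vals = np.concatenate([a, b])
        cov = self.covariates(9, [True] * 5 + [False] * 4)
        cohort = make_cohort({seg: vals for seg in SEGMENTS}, cov)
        r = subgroup_test(cohort, "sarme", "roll", "dental_mandible", welch=True)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 5 + vb / 4
        df = se2**2 / ((va / 5) ** 2 / 4 + (vb / 4) ** 2 / 3)
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        p = 2 * sps.t.sf(abs(t), df)
        assert r.mean_diff == pytest.approx(a.mean() - b.mean(), abs=1e-12)
        assert r.p_value == pytest.approx(p, abs=1e-10)
        half = sps.t.ppf(0.975, df) * np.sqrt(se2)
        assert r.ci_low == pytest.approx(r.mean_diff - half, abs=1e-10)

    def test_pooled_student_option(self):
        a = np.array([3.1, 2.4, 4.0, 3.3])
        b = np.array([1.0, 1.9, 0.4, 1.5, 2.2])
        vals = np.concatenate([a, b])
        cov = self.covariates(9, [True] * 4 + [False] * 5)
        cohort = make_cohort({seg: vals for seg in SEGMENTS}, cov)
        r = subgroup_test(cohort, "sarme", "yaw", "bony_mandible", welch=False)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert r.p_value == pytest.approx(p, abs=1e-12)

    def test_small_group_rejected_with_covariate_name(self):
        vals = np.arange(5.0)
        cov = self.covariates(5, [True] + [False] * 4)
        cohort = make_cohort({seg: vals for seg in SEGMENTS}, cov)
        with pytest.raises(StatsInputError, match="sarme"):
            subgroup_test(cohort, "sarme", "pitch", "dental_maxilla")

    def test_coverage_of_known_shift(self, rng):
        """At large n the Welch CI covers a known group shift ~95% of the
        time and the mean difference concentrates on it."""
        delta, hits, reps = 1.5, 0, 200
        diffs = []
        for _ in range(reps):
            a = rng.normal(delta, 1.0, 60)
            b = rng.normal(0.0, 2.0, 60)
            cov = self.covariates(120, [True] * 60 + [False] * 60)
            cohort = make_cohort({"dental_maxilla": np.concatenate([a, b])}, cov)
            r = subgroup_test(cohort, "sarme", "pitch", "dental_maxilla")
            hits += r.ci_low <= delta <= r.ci_high
            diffs.append(r.mean_diff)
        assert 0.90 <= hits / reps <= 0.99
        assert np.mean(diffs) == pytest.approx(delta, abs=0.1)


def test_format_p():
    assert format_p(0.0003) == "<0.001"
    assert format_p(0.027) == "0.027"
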