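"""Normality-gated paired statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from madct.stats import (
    comparison_table,
    mean_difference_ci,
    normality_gate,
    paired_test,
    render_report,
    summarize_variable,
    summary_difference,
)


def wilcoxon_exact_enumeration(diffs):
    """Independent oracle: two-sided signed-rank p by enumerating all 2^n
    sign assignments of the rank statistic (zeros dropped, ties midranked)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([
        sum(r for i, r in enumerate(ranks) if (mask >> i) & 1)
        for mask in range(2**n)
    ])
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(cdf, sf))


class TestNormalityGate:
    def test_bimodal_differences_route_nonparametric(self):
        d = np.r_[np.zeros(10), np.full(10, 5.0)] + 0.01 * np.arange(20)
        route, p = normality_gate(d)
        assert route == "nonparametric"
        assert p < 0.05

    def test_normal_quantiles_route_parametric(self):
        d = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        route, p = normality_gate(d)
        assert route == "parametric"
        assert p >= 0.05

    def test_matches_reference_shapiro_wilk(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            d = rng.normal(size=20) + rng.exponential(size=20)
            _, p = normality_gate(d)
            assert p == pytest.approx(sps.shapiro(d).pvalue, abs=1e-3)

    def test_constant_vector_is_degenerate(self):
        assert normality_gate(np.full(10, 3.0)) == ("nonparametric", 0.0)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestMeanDifferenceCI:
    def test_closed_form_small_sample(self):
        mean, lo, hi = mean_difference_ci([1.0, 2.0, 3.0])
        tcrit = sps.t.ppf(0.975, 2)
        assert mean == pytest.approx(2.0)
        assert lo == pytest.approx(2.0 - tcrit / np.sqrt(3), abs=1e-10)
        assert hi == pytest.approx(2.0 + tcrit / np.sqrt(3), abs=1e-10)
        assert (round(lo, 3), round(hi, 3)) == (-0.484, 4.484)

    def test_constant_differences_collapse(self):
        assert mean_difference_ci([2.5, 2.5, 2.5]) == (2.5, 2.5, 2.5)

    def test_antisymmetry_under_sign_flip(self):
        mean, lo, hi = mean_difference_ci([1.0, 2.0, 4.0])
        nmean, nlo, nhi = mean_difference_ci([-1.0, -2.0, -4.0])
        assert (nmean, nlo, nhi) == pytest.approx((-mean, -hi, -lo))

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            mean_difference_ci([1.0])


class TestPairedTest:
    def test_identical_visits_give_p_one(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.mean_difference == 0.0

    def test_forced_parametric_small_sample(self):
        res = paired_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], force="parametric")
        assert res.test_used == "paired_t"
        assert res.mean_difference == pytest.approx(2.0)
        assert res.p_value == pytest.approx(0.0742, abs=5e-4)
        assert res.ci_low <= res.mean_difference <= res.ci_high

    def test_forced_wilcoxon_small_sample_exact(self):
        res = paired_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], force="nonparametric")
        assert res.test_used == "wilcoxon"
        assert res.p_value == pytest.approx(0.25)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 10))
    def test_wilcoxon_exact_matches_sign_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(0.3, 1.0, size=n)  # continuous: no ties
        res = paired_test(diffs, np.zeros(n), force="nonparametric")
        assert res.p_value == pytest.approx(wilcoxon_exact_enumeration(diffs), abs=1e-12)

    def test_antisymmetry_swapping_visits(self):
        rng = np.random.default_rng(5)
        pre, post = rng.normal(10, 2, 15), rng.normal(9, 2, 15)
        a = paired_test(pre, post)
        b = paired_test(post, pre)
        assert b.mean_difference == pytest.approx(-a.mean_difference)
        assert (b.ci_low, b.ci_high) == pytest.approx((-a.ci_high, -a.ci_low))
        assert b.p_value == pytest.approx(a.p_value)

    def test_length_mismatch_and_small_n_rejected(self):
        with pytest.raises(ValueError):
            paired_test([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_test([1.0, 2.0], [1.0, 2.0])


class TestSummaries:
    def test_summary_difference_reproduces_reported_reductions(self):
        assert summary_difference(4.21, 3.69) == pytest.approx(0.52)
        assert summary_difference(1.04, 0.73) == pytest.approx(0.31)
        assert summary_difference(2.0, 2.0) == 0.0

    def test_parametric_summary(self):
        s = summarize_variable([1.0, 2.0, 3.0, 4.0], "parametric")
        assert s.mean == pytest.approx(2.5)
        assert s.sd == pytest.approx(1.29, abs=5e-3)

    def test_nonparametric_summary_linear_quantiles(self):
        s = summarize_variable([1.0, 2.0, 3.0, 4.0], "nonparametric")
        assert (s.median, s.q1, s.q3) == pytest.approx((2.5, 1.75, 3.25))

    def test_single_value_degenerate(self):
        s = summarize_variable([7.0], "parametric")
        assert s.mean == s.median == 7.0
        assert s.sd == 0.0
        with pytest.raises(ValueError):
            summarize_variable([], "parametric")


class TestComparisonTable:
    @staticmethod
    def _long_df(rng, effect=0.0, n=12):
        rows = []
        for i in range(n):
            base = rng.normal(10, 1)
            rows.append(dict(subject_id=f"s{i}", visit="pre", phase="", variable="X",
                             value=base + rng.normal(0, 0.3)))
            rows.append(dict(subject_id=f"s{i}", visit="post", phase="", variable="X",
                             value=base - effect + rng.normal(0, 0.3)))
        return pd.DataFrame(rows)

    def test_programmed_effect_is_flagged(self):
        table = comparison_table(self._long_df(np.random.default_rng(2), effect=1.0))
        row = table.iloc[0]
        assert row["significant"]
        assert row["mean_difference"] == pytest.approx(1.0, abs=0.3)
        assert row["n"] == 12

    def test_missing_pair_dropped(self):
        df = self._long_df(np.random.default_rng(3))
        df = df[~((df.subject_id == "s0") & (df.visit == "post"))]
        table = comparison_table(df)
        assert table.iloc[0]["n"] == 11

    def test_empty_variable_list_gives_empty_table(self):
        table = comparison_table(self._long_df(np.random.default_rng(4)), variables=[])
        assert table.empty

    def test_report_rendering_is_deterministic(self):
        table = comparison_table(self._long_df(np.random.default_rng(5)))
        assert render_report(table, "tsv") == render_report(table, "tsv")
        md = render_report(table, "markdown")
        assert md.startswith("| Variable |")
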