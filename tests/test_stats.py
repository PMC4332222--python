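"""Correlation, regression and group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lungfot.stats import (
    StatsError,
    compare_groups,
    correlate,
    grade_correlation,
    repeated_compare_groups,
)


class TestCorrelate:
    def test_exact_log_linear_relation(self):
        x = np.linspace(0.0, 3.0, 12)
        y = 10.0**x
        res = correlate(x, y, log_y=True)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(1.0, abs=1e-9)

    def test_antimonotone_spearman(self):
        x = np.arange(10.0)
        y = np.exp(-x)
        assert correlate(x, y).r_s == pytest.approx(-1.0)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        res = correlate(x, y)
        assert res.r2 == pytest.approx(res.r**2, abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = np.exp(x + 0.3 * rng.normal(size=30))
        a = correlate(x, y).r_s
        b = correlate(x, y**3).r_s          # strictly monotone transform
        assert a == pytest.approx(b, abs=1e-12)

    def test_log_flag_requires_positive_y(self):
        with pytest.raises(StatsError, match="positive"):
            correlate([1.0, 2.0, 3.0], [1.0, -1.0, 2.0], log_y=True)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(StatsError):
            correlate([1.0, 2.0], [1.0, 2.0])

    def test_confidence_band_brackets_fit(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 25)
        y = 1 + 2 * x + 0.1 * rng.normal(size=25)
        res = correlate(x, y)
        fit = res.intercept + res.slope * res.ci_x
        assert np.all(res.ci_low <= fit)
        assert np.all(fit <= res.ci_high)


class TestCompareGroups:
    def _table(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for grp, mu in (("a", 0.0), ("b", shift)):
            for peep in (0, 4):
                for _ in range(6):
                    rows.append({"group": grp, "peep": peep,
                                 "y": mu + rng.normal()})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        # group b is a literal copy of group a: zero main effect, p_adj = 1
        df = self._table(shift=0.0)
        a = df[df.group == "a"].copy()
        df = pd.concat([a, a.assign(group="b")], ignore_index=True)
        res = compare_groups(df, "y", ("group", "peep"))
        assert res.anova.loc["C(group)", "F"] == pytest.approx(0.0, abs=1e-12)
        assert (res.pairwise["p_adj"] == 1.0).all()

    def test_large_shift_detected(self):
        df = self._table(shift=10.0)
        res = compare_groups(df, "y", ("group", "peep"))
        assert res.anova.loc["C(group)", "PR(>F)"] < 1e-6
        assert (res.pairwise["p_adj"] < 0.001).all()

    def test_bonferroni_adjustment_definition(self):
        df = self._table(shift=1.0)
        res = compare_groups(df, "y", ("group", "peep"))
        m = res.n_comparisons
        assert np.allclose(
            res.pairwise["p_adj"], np.minimum(1.0, res.pairwise["p_raw"] * m)
        )

    def test_one_way_f_equals_squared_t(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 10,
            "y": np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)]),
        })
        res = compare_groups(df, "y", ("g",))
        t, _ = sps.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"], equal_var=True)
        assert res.anova.loc["C(g)", "F"] == pytest.approx(t**2, abs=1e-9)

    def test_tukey_kramer_path(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 8),
            "y": np.concatenate([rng.normal(m, 1, 8) for m in (0, 0, 5)]),
        })
        res = compare_groups(df, "y", ("g",), method="tukey")
        assert res.method == "tukey-kramer"
        pc = res.pairwise
        assert float(pc.loc[(pc.group1 == "a") & (pc.group2 == "c"), "p_adj"].iloc[0]) < 0.001

    def test_missing_column_rejected(self):
        with pytest.raises(StatsError, match="missing"):
            compare_groups(pd.DataFrame({"y": [1.0]}), "y", ("nope",))


class TestRepeatedCompareGroups:
    def _profiles(self, diverge, seed=0):
        # two groups of 5 subjects measured at 4 within-levels; group "b"
        # is shifted, and optionally its profile slope diverges
        rng = np.random.default_rng(seed)
        rows = []
        for grp, base, slope in (("a", 0.0, 1.0), ("b", 3.0, 1.0 + diverge)):
            for s in range(5):
                subj = f"{grp}{s}"
                offset = rng.normal(0, 0.5)
                for lvl in range(4):
                    rows.append({
                        "subject": subj, "group": grp, "level": lvl,
                        "y": base + offset + slope * lvl + rng.normal(0, 0.05),
                    })
        return pd.DataFrame(rows)

    def test_parallel_profiles_have_no_interaction(self):
        res = repeated_compare_groups(self._profiles(diverge=0.0), "y",
                                      subject="subject", within="level",
                                      between="group")
        assert res.anova.loc["C(group)", "PR(>F)"] < 0.001
        assert res.anova.loc["C(level)", "PR(>F)"] < 0.001
        assert res.anova.loc["C(level):C(group)", "PR(>F)"] > 0.05

    def test_diverging_profiles_show_interaction(self):
        res = repeated_compare_groups(self._profiles(diverge=1.0), "y",
                                      subject="subject", within="level",
                                      between="group")
        assert res.anova.loc["C(level):C(group)", "PR(>F)"] < 0.001

    def test_subject_in_two_groups_rejected(self):
        df = self._profiles(diverge=0.0)
        df.loc[df.index[:2], "group"] = "b"   # subject a0 now spans groups
        with pytest.raises(StatsError, match="constant within subject"):
            repeated_compare_groups(df, "y", subject="subject",
                                    within="level", between="group")


class TestGradeCorrelation:
    def test_perfect_separation(self):
        df = pd.DataFrame({
            "grade": np.repeat([0, 1, 2, 3], 4),
            "e_het": np.concatenate([g * 10 + np.linspace(1, 2, 4) for g in range(4)]) + 1,
        })
        res = grade_correlation(df)
        assert res.r_s > 0.95

    def test_shuffled_labels_destroy_association(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "grade": np.repeat([0, 1, 2, 3], 10),
            "e_het": np.concatenate([10.0**g + rng.random(10) for g in range(4)]),
        })
        shuffled = df.assign(grade=rng.permutation(df["grade"].to_numpy()))
        assert abs(grade_correlation(shuffled).r_s) < 0.4

    def test_single_grade_rejected(self):
        df = pd.DataFrame({"grade": [1, 1, 1], "e_het": [1.0, 2.0, 3.0]})
        with pytest.raises(StatsError, match="distinct grades"):
            grade_correlation(df)
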