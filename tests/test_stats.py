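"""Factorial / repeated-measures ANOVA, post-hoc corrections, t-tests.

The fixtures are small integer designs whose sums of squares are recomputed
here from the textbook partition formulas, independently of the fitted models.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from painephys.stats import (
    adjust_pvalues,
    posthoc,
    rm_two_way_anova,
    two_way_anova,
    unpaired_t,
)


def balanced_2x2(values):
    """3 observations per cell, cells ordered (SNI,SH),(SNI,ExEE),(sham,SH),(sham,ExEE)."""
    return pd.DataFrame(
        {
            "surgery": ["SNI"] * 6 + ["sham"] * 6,
            "housing": (["SH"] * 3 + ["ExEE"] * 3) * 2,
            "y": values,
        }
    )


def hand_twoway_ss(df):
    """Classical balanced two-way SS partition computed from cell/marginal means."""
    grand = df["y"].mean()
    ss_a = sum(
        len(sub) * (sub["y"].mean() - grand) ** 2 for _, sub in df.groupby("surgery")
    )
    ss_b = sum(
        len(sub) * (sub["y"].mean() - grand) ** 2 for _, sub in df.groupby("housing")
    )
    ss_cells = sum(
        len(sub) * (sub["y"].mean() - grand) ** 2
        for _, sub in df.groupby(["surgery", "housing"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((sub["y"] - sub["y"].mean()) ** 2).sum()
        for _, sub in df.groupby(["surgery", "housing"])
    )
    return ss_a, ss_b, ss_ab, ss_err


class TestTwoWayAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        df = balanced_2x2([5, 6, 7, 2, 3, 4, 3, 4, 5, 1, 2, 3])
        ss_a, ss_b, ss_ab, ss_err = hand_twoway_ss(df)
        df_err = 12 - 4
        res = two_way_anova(df, "y")
        assert res.effects["surgery"].F == pytest.approx((ss_a / 1) / (ss_err / df_err), abs=1e-8)
        assert res.effects["housing"].F == pytest.approx((ss_b / 1) / (ss_err / df_err), abs=1e-8)
        assert res.effects["interaction"].F == pytest.approx(
            (ss_ab / 1) / (ss_err / df_err), abs=1e-8
        )
        assert res.effects["surgery"].df2 == df_err

    def test_zero_within_cell_variance_pure_main_effect(self):
        # pure surgery effect with no residual noise: F_A capped as inf+flag,
        # housing and interaction exactly zero
        df = balanced_2x2([5, 5, 5, 5, 5, 5, 1, 1, 1, 1, 1, 1])
        res = two_way_anova(df, "y")
        assert "zero_residual_variance" in res.flags
        assert res.effects["surgery"].F == np.inf and res.effects["surgery"].p == 0.0
        assert res.effects["housing"].F == 0.0
        assert res.effects["interaction"].F == 0.0

    def test_empty_cell_rejected(self):
        df = balanced_2x2([5, 6, 7, 2, 3, 4, 3, 4, 5, 1, 2, 3])
        df = df[~((df.surgery == "sham") & (df.housing == "ExEE"))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(df, "y")

    def test_row_order_never_changes_statistics(self):
        rng = np.random.default_rng(3)
        df = balanced_2x2(rng.normal(size=12))
        base = two_way_anova(df, "y")
        shuf = two_way_anova(df.sample(frac=1.0, random_state=1), "y")
        for k in base.effects:
            assert shuf.effects[k].F == pytest.approx(base.effects[k].F, rel=1e-12)

    def test_unbalanced_design_accepted_with_type2_ss(self):
        df = balanced_2x2([5, 6, 7, 2, 3, 4, 3, 4, 5, 1, 2, 3])
        df = pd.concat([df, df.iloc[[0, 3]]], ignore_index=True)  # unbalance two cells
        res = two_way_anova(df, "y")
        assert all(np.isfinite(e.F) for e in res.effects.values())


class TestRmTwoWayAnova:
    @staticmethod
    def _table(values):
        # 2 groups x 4 subjects x 3 timepoints, values in subject-major order
        rows = []
        i = 0
        for g in ("A", "B"):
            for s in range(4):
                for t in (1, 2, 3):
                    rows.append(
                        {"animal_id": f"{g}{s}", "group": g,
                         "timepoint_day": t, "y": values[i]}
                    )
                    i += 1
        return pd.DataFrame(rows)

    def test_matches_hand_partitioned_ss(self):
        vals = [3, 4, 6, 2, 4, 5, 4, 5, 7, 3, 3, 6,
                6, 8, 9, 7, 7, 10, 5, 8, 8, 6, 9, 11]
        df = self._table(vals)
        n_subj, g, t = 8, 2, 3
        grand = df["y"].mean()
        subj_means = df.groupby("animal_id")["y"].mean()
        group_means = df.groupby("group")["y"].mean()
        time_means = df.groupby("timepoint_day")["y"].mean()
        cell_means = df.groupby(["group", "timepoint_day"])["y"].mean()
        ss_group = t * sum(4 * (group_means[gr] - grand) ** 2 for gr in ("A", "B"))
        ss_subj_within = t * sum(
            (subj_means[s] - group_means[s[0]]) ** 2 for s in subj_means.index
        )
        ss_time = n_subj * sum((time_means[tt] - grand) ** 2 for tt in (1, 2, 3))
        ss_int = sum(
            4 * (cell_means[(gr, tt)] - group_means[gr] - time_means[tt] + grand) ** 2
            for gr in ("A", "B") for tt in (1, 2, 3)
        )
        ss_total = ((df["y"] - grand) ** 2).sum()
        ss_err = ss_total - ss_group - ss_subj_within - ss_time - ss_int
        f_group = (ss_group / (g - 1)) / (ss_subj_within / (n_subj - g))
        f_time = (ss_time / (t - 1)) / (ss_err / ((n_subj - g) * (t - 1)))
        f_int = (ss_int / ((g - 1) * (t - 1))) / (ss_err / ((n_subj - g) * (t - 1)))

        res = rm_two_way_anova(df, "y")
        assert res.effects["between"].F == pytest.approx(f_group, rel=1e-8)
        assert res.effects["within"].F == pytest.approx(f_time, rel=1e-8)
        assert res.effects["interaction"].F == pytest.approx(f_int, rel=1e-8)

    def test_agrees_with_pingouin_on_wellbehaved_data(self):
        import pingouin as pg

        rng = np.random.default_rng(21)
        df = self._table(list(rng.normal(loc=np.repeat([10.0, 13.0], 12), scale=1.5)))
        res = rm_two_way_anova(df, "y")
        ref = pg.mixed_anova(
            data=df, dv="y", within="timepoint_day",
            subject="animal_id", between="group",
        ).set_index("Source")
        assert res.effects["between"].F == pytest.approx(float(ref.loc["group", "F"]), rel=1e-8)
        assert res.effects["within"].F == pytest.approx(
            float(ref.loc["timepoint_day", "F"]), rel=1e-8
        )
        assert res.effects["interaction"].F == pytest.approx(
            float(ref.loc["Interaction", "F"]), rel=1e-8
        )

    def test_greenhouse_geisser_option_shrinks_dfs(self):
        rng = np.random.default_rng(22)
        base = rng.normal(size=24) + np.tile([0.0, 2.0, 5.0], 8)
        res = rm_two_way_anova(self._table(list(base)), "y")
        gg = rm_two_way_anova(self._table(list(base)), "y", gg_correction=True)
        assert gg.effects["within"].df1 <= res.effects["within"].df1
        assert gg.effects["within"].p >= res.effects["within"].p - 1e-12

    def test_flat_data_gives_zero_effects(self):
        df = self._table([5.0] * 24)
        res = rm_two_way_anova(df, "y")
        assert all(e.F == 0.0 and e.p == 1.0 for e in res.effects.values())

    def test_constant_group_offset_dominates_between_effect(self):
        vals = [1, 1, 1] * 4 + [4, 4, 4] * 4
        df = self._table([float(v) for v in vals])
        res = rm_two_way_anova(df, "y")
        assert res.effects["between"].F > 1e3 or res.effects["between"].p < 1e-6
        assert res.effects["interaction"].F == pytest.approx(0.0, abs=1e-8)

    def test_incomplete_subject_dropped_with_warning(self):
        df = self._table(list(np.arange(24.0)))
        df = df.drop(df[(df.animal_id == "A0") & (df.timepoint_day == 3)].index)
        with pytest.warns(UserWarning, match="A0"):
            res = rm_two_way_anova(df, "y")
        assert res.cell_means["n"].max() == 4  # A has 3 complete subjects left


class TestPosthoc:
    def test_holm_sidak_matches_stepdown_formula(self):
        raw = np.array([0.01, 0.02, 0.03, 0.5])
        adj = adjust_pvalues(raw, "holm_sidak")
        # hand step-down: 1-(1-p_(i))^(m-i+1), enforced monotone
        m = len(raw)
        expected = []
        running = 0.0
        for i, p in enumerate(sorted(raw)):
            running = max(running, 1.0 - (1.0 - p) ** (m - i))
            expected.append(running)
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_bky_two_stage_known_values_with_raw_floor(self):
        raw = np.array([0.01, 0.02, 0.03, 0.5])
        unclipped = adjust_pvalues(raw, "bky_fdr", clip_at_raw=False)
        clipped = adjust_pvalues(raw, "bky_fdr")
        # the adaptive stage may undercut the raw p; the default reporting floors it
        assert unclipped[3] < raw[3]
        np.testing.assert_allclose(clipped, np.maximum(unclipped, raw))

    def test_identical_groups_are_never_rejected(self):
        df = pd.DataFrame(
            {"surgery": ["SNI"] * 6 + ["sham"] * 6,
             "housing": (["SH"] * 3 + ["ExEE"] * 3) * 2,
             "y": [4.0, 4.0, 4.0] * 4}
        )
        for method in ("tukey", "holm_sidak", "bky_fdr"):
            tab = posthoc(df, "y", method)
            assert (tab["p_adj"] == 1.0).all()
            assert not tab["reject"].any()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_adjusted_p_at_least_raw_p_under_all_methods(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {"surgery": rng.choice(["SNI", "sham"], size=24),
             "housing": rng.choice(["SH", "ExEE"], size=24),
             "y": rng.normal(size=24)}
        )
        # make sure all four cells are populated
        df.iloc[:4, 0] = ["SNI", "SNI", "sham", "sham"]
        df.iloc[:4, 1] = ["SH", "ExEE", "SH", "ExEE"]
        for method in ("tukey", "holm_sidak", "bky_fdr"):
            tab = posthoc(df, "y", method)
            assert (tab["p_adj"] >= tab["p_raw"] - 1e-12).all()
            assert tab["p_adj"].between(0, 1).all()

    def test_tukey_agrees_with_statsmodels_reference(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {"surgery": ["SNI"] * 8 + ["sham"] * 8,
             "housing": (["SH"] * 4 + ["ExEE"] * 4) * 2,
             "y": rng.normal(loc=np.repeat([0, 1, 0.5, 0], 4), size=16)}
        )
        tab = posthoc(df, "y", "tukey").sort_values(["group1", "group2"])
        cell = df["surgery"] + "-" + df["housing"]
        ref = pairwise_tukeyhsd(df["y"], cell)
        ref_df = pd.DataFrame(
            ref.summary().data[1:], columns=ref.summary().data[0]
        ).sort_values(["group1", "group2"])
        np.testing.assert_allclose(
            tab["p_adj"].to_numpy(dtype=float),
            ref_df["p-adj"].to_numpy(dtype=float),
            atol=2e-3,  # statsmodels rounds its table to 4 digits
        )

    def test_unknown_method_rejected(self):
        df = balanced_2x2([5, 6, 7, 2, 3, 4, 3, 4, 5, 1, 2, 3])
        with pytest.raises(ValueError):
            posthoc(df, "y", "bonferroni-ish")


class TestUnpairedT:
    def test_identical_groups(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_textbook_pooled_formula(self):
        # A=(1,2,3), B=(4,5,6): diff=-3, pooled var=1, se=sqrt(2/3)
        res = unpaired_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert res.df == 4

    def test_student_df_is_n_minus_2(self):
        rng = np.random.default_rng(0)
        res = unpaired_t(rng.normal(size=16), rng.normal(size=14))
        assert res.df == 28

    def test_zero_variance_conventions(self):
        res = unpaired_t([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0 and res.flags
        res2 = unpaired_t([2.0, 2.0], [3.0, 3.0])
        assert np.isinf(res2.t) and res2.p == 0.0

    def test_welch_option_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.05, 0.95]
        b = [2.0, 5.0, -1.0, 4.0, 0.0]
        student = unpaired_t(a, b, equal_var=True)
        welch = unpaired_t(a, b, equal_var=False)
        assert welch.df < student.df
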