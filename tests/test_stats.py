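import math

import numpy as np
import pandas as pd
import pytest

from gazegraph import (correlate_with_age, mixed_anova, paired_condition_t,
                       paired_phase_t, pairwise_t, report_posthoc,
                       report_tables)


def metric_table(rows):
    """rows: (pid, age, group, window, condition, metric, value)."""
    return pd.DataFrame(rows, columns=[
        "participant_id", "age_years", "age_group", "window", "condition",
        "metric", "value"])


def balanced_design(values):
    """values[group][phase] = list of per-participant values, equal n."""
    rows = []
    ages = {"4-6": 5.0, "6-8": 7.0, "8-10": 9.0}
    pid = 0
    for group, phases in values.items():
        n = len(next(iter(phases.values())))
        for i in range(n):
            pid += 1
            for phase, vals in phases.items():
                rows.append((f"P{pid:03d}", ages[group] + 0.1 * i, group,
                             phase, "general", "centrality", vals[i]))
    return metric_table(rows)


def anova_oracle(data):
    """From-scratch sums-of-squares for a balanced two-way mixed design.

    data[group] = 2-D array (n_subjects, n_phases).  Returns dict of
    (F, df_num, df_den) for the between, within and interaction effects.
    """
    groups = list(data.values())
    a = len(groups)
    n = groups[0].shape[0]
    b = groups[0].shape[1]
    grand = np.mean([g.mean() for g in groups])

    ss_a = n * b * sum((g.mean() - grand) ** 2 for g in groups)
    ss_subj = b * sum(((g.mean(axis=1) - g.mean()) ** 2).sum() for g in groups)
    phase_means = np.mean([g.mean(axis=0) for g in groups], axis=0)
    ss_b = a * n * ((phase_means - grand) ** 2).sum()
    ss_ab = n * sum(
        ((g.mean(axis=0) - g.mean() - phase_means + grand) ** 2).sum()
        for g in groups)
    ss_tot = sum(((g - grand) ** 2).sum() for g in groups)
    ss_err = ss_tot - ss_a - ss_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, a * (n - 1)
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err = a * (n - 1) * (b - 1)

    def f(ss_num, df_num, ss_den, df_den):
        num, den = ss_num / df_num, ss_den / df_den
        if den == 0:
            return (0.0 if num == 0 else math.inf), df_num, df_den
        return num / den, df_num, df_den

    return {"group": f(ss_a, df_a, ss_subj, df_subj),
            "phase": f(ss_b, df_b, ss_err, df_err),
            "interaction": f(ss_ab, df_ab, ss_err, df_err)}


class TestCorrelateWithAge:
    def test_perfectly_linear_values_give_r_one(self):
        rows = [(f"P{i}", 4 + i, "4-6" if i < 2 else "8-10", "early",
                 "general", "centrality", 10.0 + 2 * i) for i in range(5)]
        r, p = correlate_with_age(metric_table(rows), "centrality", "early",
                                  "general")
        assert r == pytest.approx(1.0)

    def test_age_independent_values_show_no_correlation(self):
        rng = np.random.default_rng(3)
        rows = [(f"P{i}", 4 + 6 * rng.random(), "4-6", "early", "general",
                 "centrality", 100 + rng.normal()) for i in range(200)]
        r, p = correlate_with_age(metric_table(rows), "centrality", "early",
                                  "general")
        assert abs(r) < 0.2

    def test_two_participants_is_an_error(self):
        rows = [("P1", 5.0, "4-6", "early", "general", "centrality", 1.0),
                ("P2", 7.0, "6-8", "early", "general", "centrality", 2.0)]
        with pytest.raises(ValueError, match=">= 3"):
            correlate_with_age(metric_table(rows), "centrality", "early",
                               "general")

    def test_zero_variance_names_the_degenerate_variable(self):
        rows = [(f"P{i}", 4.0 + i, "4-6", "early", "general", "centrality",
                 5.0) for i in range(4)]
        with pytest.raises(ValueError, match="centrality"):
            correlate_with_age(metric_table(rows), "centrality", "early",
                               "general")


class TestMixedAnova:
    def test_all_equal_values_give_zero_f(self):
        table = balanced_design({
            g: {"early": [7.0, 7.0, 7.0], "late": [7.0, 7.0, 7.0]}
            for g in ("4-6", "6-8", "8-10")})
        for res in mixed_anova(table, "centrality", "general"):
            assert res.F == 0.0 and res.p == 1.0

    def test_pure_phase_effect_detected(self):
        base = [10.0, 12.0, 14.0, 11.0]
        table = balanced_design({
            g: {"early": [v + 5 for v in base], "late": base}
            for g in ("4-6", "6-8", "8-10")})
        by_effect = {r.effect: r for r in
                     mixed_anova(table, "centrality", "general")}
        assert math.isinf(by_effect["phase"].F) and by_effect["phase"].p == 0.0
        assert by_effect["group"].F == 0.0
        assert by_effect["interaction"].F == 0.0

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(17)
        data = {g: rng.integers(0, 20, size=(5, 2)).astype(float)
                for g in ("4-6", "6-8", "8-10")}
        table = balanced_design({
            g: {"early": list(arr[:, 0]), "late": list(arr[:, 1])}
            for g, arr in data.items()})
        expected = anova_oracle(data)
        for res in mixed_anova(table, "centrality", "general"):
            f, dfn, dfd = expected[res.effect]
            assert res.F == pytest.approx(f, abs=1e-9)
            assert (res.df_num, res.df_den) == (dfn, dfd)

    def test_group_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(23)
        data = {g: rng.normal(loc, 1.0, size=(6, 2))
                for g, loc in (("4-6", 10.0), ("8-10", 12.0))}
        table = balanced_design({
            g: {"early": list(arr[:, 0]), "late": list(arr[:, 1])}
            for g, arr in data.items()})
        group_f = {r.effect: r.F for r in
                   mixed_anova(table, "centrality", "general")}["group"]
        means = {g: arr.mean(axis=1) for g, arr in data.items()}
        t = (means["4-6"].mean() - means["8-10"].mean()) / np.sqrt(
            (means["4-6"].var(ddof=1) + means["8-10"].var(ddof=1)) / 6)
        assert group_f == pytest.approx(t ** 2, rel=1e-9)

    def test_participant_missing_a_phase_is_listed(self):
        table = balanced_design({
            g: {"early": [1.0, 2.0], "late": [3.0, 4.0]}
            for g in ("4-6", "6-8", "8-10")})
        table = table[~((table.participant_id == "P002")
                        & (table.window == "late"))]
        with pytest.raises(ValueError, match="P002"):
            mixed_anova(table, "centrality", "general")


class TestPairwiseT:
    def test_identical_groups_give_t_zero(self):
        table = balanced_design({"4-6": {"early": [1.0, 2.0, 3.0]},
                                 "6-8": {"early": [1.0, 2.0, 3.0]}})
        t, df, p = pairwise_t(table, "centrality", "4-6", "6-8", "early",
                              "general")
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        table = balanced_design({"4-6": {"early": [2.0, 4.0]},
                                 "6-8": {"early": [6.0, 8.0]}})
        t, df, p = pairwise_t(table, "centrality", "4-6", "6-8", "early",
                              "general")
        assert t == pytest.approx(-2.8284271247461903, abs=1e-9)
        assert df == 2

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(5)
        table = balanced_design({
            "4-6": {"early": list(rng.normal(0, 1e-3, 4))},
            "6-8": {"early": list(1 + rng.normal(0, 1e-3, 4))}})
        t, df, p = pairwise_t(table, "centrality", "4-6", "6-8", "early",
                              "general")
        assert abs(t) > 100 and p < 1e-4

    def test_degenerate_variance_is_an_error(self):
        table = balanced_design({"4-6": {"early": [1.0, 1.0]},
                                 "6-8": {"early": [2.0, 2.0]}})
        with pytest.raises(ValueError, match="variance"):
            pairwise_t(table, "centrality", "4-6", "6-8", "early", "general")

    def test_paired_phase_variant_matches_closed_form(self):
        table = balanced_design({
            "4-6": {"early": [5.0, 7.0, 9.0], "late": [4.0, 5.0, 6.0]}})
        t, df, p = paired_phase_t(table, "centrality", "4-6", "general")
        d = np.array([1.0, 2.0, 3.0])
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expected, abs=1e-12)
        assert df == 2


class TestConditionContrast:
    def test_paired_green_vs_normal(self):
        rows = []
        for i, (g, n) in enumerate([(10.0, 8.0), (12.0, 9.0), (11.0, 10.0)]):
            rows.append((f"P{i}", 5.0, "4-6", "early", "green",
                         "centrality", g))
            rows.append((f"P{i}", 5.0, "4-6", "early", "normal",
                         "centrality", n))
        t, df, p = paired_condition_t(metric_table(rows), "centrality",
                                      "early")
        assert t > 0 and df == 2


class TestReports:
    def test_cell_means_and_counts(self):
        table = balanced_design({"4-6": {"early": [100.0, 200.0]}})
        rep = report_tables(table)
        row = rep.iloc[0]
        assert row["mean"] == 150.0 and row["n"] == 2

    def test_empty_cell_reported_missing_not_zero(self):
        table = balanced_design({"4-6": {"early": [1.0, 2.0]},
                                 "6-8": {"late": [3.0, 4.0]}})
        rep = report_tables(table)
        empty = rep[(rep.age_group == "4-6") & (rep.window == "late")]
        assert empty["n"].iloc[0] == 0
        assert np.isnan(empty["mean"].iloc[0])

    def test_full_cohort_report_shape(self, small_cohort):
        from gazegraph import cohort_metrics
        table = cohort_metrics(small_cohort.scanpaths, small_cohort.cohort)
        rep = report_tables(table)
        assert len(rep) == 3 * 3 * 3 * 2  # groups x windows x conditions x metrics
        assert rep["n"].min() > 0

    def test_posthoc_flags_uncorrected_and_holm_option(self):
        table = balanced_design({
            "4-6": {"early": [1.0, 2.0, 3.0]},
            "6-8": {"early": [2.0, 3.5, 4.0]},
            "8-10": {"early": [4.0, 5.0, 6.5]}})
        rep = report_posthoc(table, "centrality", "early", "general")
        assert set(rep["p_kind"]) == {"uncorrected"}
        assert "p_holm" not in rep.columns
        holm = report_posthoc(table, "centrality", "early", "general",
                              correction="holm")
        assert (holm["p_holm"] >= holm["p"] - 1e-12).all()
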