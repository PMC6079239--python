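"""Statistical battery: exact tests, rank tests, ANOVA/SNK, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ca3ltp.stats import (ContingencyTable, fisher_exact_two_sided, chi_square_2x2,
                          mann_whitney_u, wilcoxon_signed_rank, kruskal_wallis,
                          anova_with_posthoc, two_way_anova,
                          pearson_correlation_test, build_contingency, round_p)
from ca3ltp.plasticity import PlasticityOutcome

from conftest import fisher_two_sided_enumeration


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[12, 34], [0, 25]], 0.006),
        ([[23, 23], [3, 22]], 0.002),
        ([[1, 18], [7, 12]], 0.042),
        ([[1, 7], [2, 7]], 1.000),
        ([[8, 0], [6, 3]], 0.206),
        ([[4, 74], [1, 10]], 0.491),
        ([[35, 43], [3, 8]], 0.341),
        ([[5, 5], [5, 5]], 1.000),
    ])
    def test_reported_contingency_p_values(self, table, expected):
        res = fisher_exact_two_sided(table)
        assert round_p(res.p_value) == pytest.approx(expected, abs=5e-4)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_equals_enumeration_for_small_margins(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        res = fisher_exact_two_sided([[a, b], [c, d]])
        assert res.p_value == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-7)

    def test_empty_margin_degenerate(self):
        res = fisher_exact_two_sided([[0, 5], [0, 7]])
        assert res.p_value == 1.0
        assert res.extra.get("degenerate")


class TestChiSquare:
    @pytest.mark.parametrize("table,expected", [
        ([[5, 81], [12, 34]], 0.002),   # baseline prevalence 5/86 vs 12/46
        ([[5, 96], [7, 25]], 0.011),    # pooled control without vs with D-AP5
    ])
    def test_reported_yates_p_values(self, table, expected):
        res = chi_square_2x2(table)
        assert round_p(res.p_value) == pytest.approx(expected, abs=5e-4)

    def test_balanced_table_statistic_zero(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_correction_never_increases_statistic(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(1, 60, size=4)
            table = [[t[0], t[1]], [t[2], t[3]]]
            yates = chi_square_2x2(table, continuity_correction=True)
            plain = chi_square_2x2(table, continuity_correction=False)
            assert yates.statistic <= plain.statistic + 1e-12

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            chi_square_2x2([[0, 5], [0, 7]])


class TestRankTests:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)
        assert "asymptotic" in res.method  # ties force the midrank approximation

    def test_fully_separated_small_samples(self):
        """[1,2,3] vs [4,5,6]: U = 0, exact two-sided p = 2/20."""
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    def test_wilcoxon_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_wilcoxon_detects_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        res = wilcoxon_signed_rank(x + 2.0, x)
        assert res.p_value < 0.001

    def test_kruskal_wallis_reports_h_and_df(self):
        rng = np.random.default_rng(3)
        g = [rng.normal(size=12) for _ in range(5)]
        res = kruskal_wallis(*g)
        assert res.extra["df"] == 4
        assert 0 <= res.p_value <= 1


class TestAnovaSnk:
    def test_identical_groups_nothing_flagged(self):
        g = [1.0, 2.0, 3.0, 4.0]
        anova, pairs = anova_with_posthoc({"a": g, "b": g, "c": g})
        assert anova.statistic == pytest.approx(0.0, abs=1e-12)
        assert not any(p.significant for p in pairs)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_widest_snk_step_matches_tukey(self, seed):
        """For k = 3 the widest SNK comparison equals the Tukey HSD decision."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": rng.normal(i * 0.8, 1.0, 12) for i in range(3)}
        _, pairs = anova_with_posthoc(groups)
        widest = next(p for p in pairs if p.span == 3)
        data = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), 12)
        tk = pairwise_tukeyhsd(data, labs, alpha=0.05)
        tk_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        means = {k: np.mean(v) for k, v in groups.items()}
        lo = min(means, key=means.get)
        hi = max(means, key=means.get)
        row = tk_df[((tk_df.group1 == lo) & (tk_df.group2 == hi)) |
                    ((tk_df.group1 == hi) & (tk_df.group2 == lo))]
        assert bool(row.reject.iloc[0]) == widest.significant

    def test_reported_nmdar_subgroup_separation_rate(self):
        """At the reported means/SEM/n, SNK separates N3 from N1 and N2 often.

        A power simulation at these effect sizes gives ~0.48 (N3 vs N1)
        and ~0.60 (N3 vs N2) flag rates; the test checks those levels.
        """
        rng = np.random.default_rng(12)
        reps = 300
        hit_31 = hit_32 = 0
        for _ in range(reps):
            groups = {"N1": rng.normal(127, 14 * np.sqrt(13), 13),
                      "N2": rng.normal(119, 12 * np.sqrt(13), 13),
                      "N3": rng.normal(168, 15 * np.sqrt(14), 14)}
            _, pairs = anova_with_posthoc(groups)
            flags = {frozenset(p.groups): p.significant for p in pairs}
            hit_31 += flags.get(frozenset(("N1", "N3")), False)
            hit_32 += flags.get(frozenset(("N2", "N3")), False)
        assert hit_32 / reps > 0.5
        assert hit_31 / reps > 0.35

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            anova_with_posthoc({"a": [1.0], "b": [1, 2], "c": [3, 4]})


class TestTwoWayAnova:
    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": np.arange(8.0), "a": ["x"] * 8,
                           "b": ["p", "q"] * 4})
        with pytest.raises(ValueError, match="two levels"):
            two_way_anova(df, "y", "a", "b")

    def test_empty_cell_with_interaction_rejected(self):
        df = pd.DataFrame({"y": np.arange(6.0),
                           "a": ["x", "x", "x", "z", "z", "z"],
                           "b": ["p", "p", "p", "q", "q", "q"]})
        with pytest.raises(ValueError, match="empty"):
            two_way_anova(df, "y", "a", "b")

    def test_injected_effect_detected_null_factor_quiet(self):
        """A strong factor-B effect is flagged; the null factor A rarely is."""
        rng = np.random.default_rng(7)
        hits_b, hits_a = 0, 0
        reps = 40
        for _ in range(reps):
            a = np.repeat(["a1", "a2"], 20)
            b = np.tile(np.repeat(["low", "high"], 10), 2)
            y = rng.normal(size=40) + np.where(b == "high", 2.0, 0.0)
            res = two_way_anova(pd.DataFrame({"y": y, "a": a, "b": b}), "y", "a", "b")
            hits_b += res["b"].p_value < 0.05
            hits_a += res["a"].p_value < 0.05
        assert hits_b >= reps * 0.9
        assert hits_a <= reps * 0.25


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_correlation_test(x, x).statistic == pytest.approx(1.0)
        assert pearson_correlation_test(x, -x).statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation_test([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_direct_formula(self, seed):
        """r and the t-test p equal the standardized-product formula."""
        from scipy.stats import t as tdist
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = pearson_correlation_test(x, y)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        r = float(np.sum(zx * zy) / (len(x) - 1))
        tstat = r * np.sqrt((len(x) - 2) / (1 - r ** 2))
        p = 2 * tdist.sf(abs(tstat), len(x) - 2)
        assert res.statistic == pytest.approx(r, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)


class TestBuildContingency:
    @staticmethod
    def _outcome(i, drug, present_b, present_a):
        return PlasticityOutcome(slice_id=f"s{i}", group="N1", pathway="A/C",
                                 drug=drug, ap_present_before=present_b,
                                 ap_present_after=present_a)

    def test_reproduces_reported_nmdar_rows(self):
        outcomes = []
        i = 0
        for present, n in ((True, 12), (False, 34)):
            for _ in range(n):
                outcomes.append(self._outcome(i, "none", present, None)); i += 1
        for _ in range(25):
            outcomes.append(self._outcome(i, "D-AP5", False, None)); i += 1
        t = build_contingency(outcomes, lambda o: o.drug, "before",
                              row_labels=("none", "D-AP5"))
        assert t.to_array().tolist() == [[12, 34], [0, 25]]

        outcomes = []
        i = 0
        for present, n in ((True, 23), (False, 23)):
            for _ in range(n):
                outcomes.append(self._outcome(i, "none", None, present)); i += 1
        for present, n in ((True, 3), (False, 22)):
            for _ in range(n):
                outcomes.append(self._outcome(i, "D-AP5", None, present)); i += 1
        t = build_contingency(outcomes, lambda o: o.drug, "after",
                              row_labels=("none", "D-AP5"))
        assert t.to_array().tolist() == [[23, 23], [3, 22]]

    def test_all_absent_cohort(self):
        outcomes = [self._outcome(i, "none" if i < 4 else "D-AP5", False, None)
                    for i in range(9)]
        t = build_contingency(outcomes, lambda o: o.drug, "before",
                              row_labels=("none", "D-AP5"))
        assert t.to_array().tolist() == [[0, 4], [0, 5]]

    def test_missing_phase_excluded_with_warning(self):
        outcomes = [self._outcome(0, "none", True, None),
                    self._outcome(1, "none", None, None),
                    self._outcome(2, "D-AP5", False, None)]
        with pytest.warns(UserWarning, match="excluded"):
            t = build_contingency(outcomes, lambda o: o.drug, "before",
                                  row_labels=("none", "D-AP5"))
        assert t.n == 2

    def test_permuting_presence_preserves_margins(self):
        rng = np.random.default_rng(0)
        flags = rng.random(30) < 0.4
        drugs = np.where(np.arange(30) < 18, "none", "D-AP5")
        def table(fl):
            outcomes = [self._outcome(i, d, bool(f), None)
                        for i, (d, f) in enumerate(zip(drugs, fl))]
            return build_contingency(outcomes, lambda o: o.drug, "before",
                                     row_labels=("none", "D-AP5")).to_array()
        t1 = table(flags)
        t2 = table(rng.permutation(flags))
        assert t1.sum() == t2.sum()
        assert np.array_equal(t1.sum(axis=1), t2.sum(axis=1))  # row margins fixed
        assert t1.sum(axis=0).sum() == t2.sum(axis=0).sum()
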