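import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from irllc import (
    dunn_bonferroni,
    friedman_omnibus,
    group_compare_independent,
    normality_screen,
    paired_compare,
    run_paper_battery,
)

from oracles import kruskal_exact_p, signed_rank_exact_p


class TestNormalityScreen:
    def test_gaussian_samples_usually_flagged_normal(self):
        flags = []
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 200)
            flags.append(normality_screen(x)[1])
        assert np.mean(flags) >= 0.90  # nominal type-I error 5%

    def test_exponential_sample_flagged_non_normal(self):
        x = np.random.default_rng(0).exponential(1.0, 200)
        p, is_normal = normality_screen(x)
        assert not is_normal and p < 1e-6

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_screen([1.0, 1.0, 1.0, 1.0])

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])


class TestPairedCompare:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        rep = paired_compare(x, x, route="nonparametric")
        assert rep.p_raw == 1.0 and "zero" in rep.note

    def test_constant_nonzero_differences_degenerate_t(self):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        rep = paired_compare(x, x - 1.0, route="parametric")
        assert np.isnan(rep.statistic) and "degenerate" in rep.note

    @pytest.mark.parametrize(
        "diffs",
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, -6.0],
            [0.3, -1.2, 2.4, -0.7, 1.9, 0.5, -2.2],
            [5.0, 4.0, -3.0, 2.0, -1.0, 6.0, 7.0, -8.0],
        ],
    )
    def test_exact_signed_rank_matches_enumeration(self, diffs):
        d = np.asarray(diffs)
        rep = paired_compare(d, np.zeros_like(d), route="nonparametric")
        assert rep.p_raw == pytest.approx(signed_rank_exact_p(d), abs=1e-12)

    def test_frozen_exact_example(self):
        # enumeration of all 64 sign assignments of ranks 1..6
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -6.0])
        rep = paired_compare(d, np.zeros_like(d), route="nonparametric")
        assert rep.p_raw == pytest.approx(0.4375, abs=1e-12)

    def test_pairwise_deletion_and_minimum_n(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, np.nan, 4.0, 7.0])
        with pytest.raises(ValueError, match=">= 5"):
            paired_compare(x, y)

    def test_auto_route_picks_t_for_gaussian_differences(self):
        r = np.random.default_rng(5)
        x = r.normal(0, 1, 60)
        y = x + r.normal(0.2, 0.5, 60)
        assert paired_compare(x, y, route="auto").test == "paired_t"


class TestFriedman:
    def test_maximal_separation_statistic(self):
        # ten subjects ranking three conditions identically: chi2 = 20
        table = np.tile([1.0, 2.0, 3.0], (10, 1))
        rep = friedman_omnibus(table)
        assert rep.statistic == pytest.approx(20.0, rel=1e-12)
        assert rep.p_raw < 1e-4

    def test_fully_tied_rows_give_zero_statistic(self):
        rep = friedman_omnibus(np.ones((10, 3)))
        assert rep.statistic == 0.0 and rep.p_raw == 1.0

    def test_agrees_with_scipy_on_untied_data(self, rng):
        table = rng.normal(size=(20, 4))
        rep = friedman_omnibus(table)
        ref = sps.friedmanchisquare(*table.T)
        assert rep.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert rep.p_raw == pytest.approx(ref.pvalue, rel=1e-10)

    def test_listwise_deletion_reported(self, rng):
        table = rng.normal(size=(12, 3))
        table[3, 1] = np.nan
        rep = friedman_omnibus(table)
        assert rep.n == 11 and "1 incomplete" in rep.note

    def test_needs_three_conditions(self):
        with pytest.raises(ValueError):
            friedman_omnibus(np.zeros((5, 2)))


class TestDunnBonferroni:
    def _table(self, rng, n=20, k=4):
        return pd.DataFrame(rng.normal(size=(n, k)), columns=list("ABCD"))

    def test_adjustment_arithmetic(self):
        # p_raw 0.01 with m = 8 -> 0.08; p_raw 0.4 -> capped at 1
        assert min(1.0, 8 * 0.01) == pytest.approx(0.08)
        rng = np.random.default_rng(2)
        table = self._table(rng)
        reps = dunn_bonferroni(table, [("A", "D"), ("B", "D"), ("C", "D")])
        for rep in reps:
            assert rep.p_adjusted == pytest.approx(min(1.0, 3 * rep.p_raw))

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_bonferroni_dominance(self, seed):
        rng = np.random.default_rng(seed)
        table = self._table(rng, n=10)
        for rep in dunn_bonferroni(table, [("A", "B"), ("C", "D")]):
            assert rep.p_adjusted >= rep.p_raw
            assert rep.p_adjusted <= 1.0

    def test_unknown_comparison_rejected(self, rng):
        with pytest.raises(ValueError, match="not in table"):
            dunn_bonferroni(self._table(rng), [("A", "Z")])


class TestKruskalWallis:
    def test_identical_groups_no_evidence(self):
        rep = group_compare_independent([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_raw == 1.0

    def test_separated_groups_exact_permutation_p(self):
        rep = group_compare_independent([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert rep.statistic == pytest.approx(3.857142857, rel=1e-9)
        assert rep.p_raw == pytest.approx(0.1, abs=1e-12)  # 2 of C(6,3)=20 assignments
        assert "exact" in rep.note

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        groups = [r.normal(0, 1, 3), r.normal(0.5, 1, 4)]
        rep = group_compare_independent(groups)
        assert rep.p_raw == pytest.approx(kruskal_exact_p(groups), abs=1e-12)

    def test_large_samples_match_scipy_chi_square(self, rng):
        groups = [rng.normal(0, 1, 15), rng.normal(0.3, 1, 15), rng.normal(0, 1.5, 15)]
        rep = group_compare_independent(groups)
        ref = sps.kruskal(*groups)
        assert rep.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert rep.p_raw == pytest.approx(ref.pvalue, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n = 2"):
            group_compare_independent([[1.0, 2.0], [3.0, 4.0, 5.0]])


def _toy_table(rng, n=12, effect=0.8):
    conditions = ["TI148", "TI228", "TI1743", "VIBE"]
    rows = []
    entities = ["CRC"] * 6 + ["HCC"] * 6
    for i in range(n):
        base = rng.normal(0.3, 0.05)
        for cond in conditions:
            bump = effect if cond in ("TI148", "TI228") else 0.0
            rows.append(
                {
                    "lesion_id": f"L{i:03d}",
                    "entity": entities[i],
                    "condition": cond,
                    "llc": abs(base + bump + rng.normal(0, 0.05)),
                    "t1_lesion_ms": rng.normal(1187, 100),
                    "t1_liver_ms": rng.normal(654, 50),
                }
            )
    return pd.DataFrame(rows)


class TestBattery:
    def test_structure_and_subgroups(self, rng):
        table = _toy_table(rng)
        out = run_paper_battery(table)
        assert set(out.llc_summary.index) == {"TI148", "TI228", "TI1743", "VIBE"}
        tests = {r.test for r in out.reports}
        assert {"friedman", "dunn_bonferroni"} <= tests
        assert set(out.subgroups) == {"CRC", "HCC"}
        assert any("T1 lesion vs liver" in r.comparison for r in out.reports)

    def test_detects_short_ti_advantage(self, rng):
        out = run_paper_battery(_toy_table(rng, effect=0.8))
        short = [
            r for r in out.reports
            if r.test == "dunn_bonferroni" and "TI148 vs VIBE" in r.comparison
        ]
        assert short and short[0].p_adjusted <= 0.05

    def test_single_entity_cohort_skips_other_subgroups(self, rng):
        table = _toy_table(rng)
        table["entity"] = "CRC"
        out = run_paper_battery(table)
        assert set(out.subgroups) == {"CRC"}

    def test_adjusted_never_below_raw(self, rng):
        out = run_paper_battery(_toy_table(rng))
        for rep in out.reports:
            if not np.isnan(rep.p_adjusted):
                assert rep.p_adjusted >= rep.p_raw
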