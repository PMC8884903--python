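"""Statistical primitives and the candidate-suppressor catalog."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test

from metascreen.cohort import (
    CohortData,
    HomologMap,
    candidate_catalog,
    fold_change_ddct,
    log_rank,
    map_homologs,
    median_split,
    read_homolog_map,
    screen_vs_catalog,
    two_sample_t,
    write_cohort,
)
from metascreen.cohort import read_cohort
from metascreen.simulate import CohortSimConfig, simulate_cohort

from oracles import event_table_logrank, pooled_t_formula, sort_based_median_split


class TestTwoSampleT:
    def test_identical_vectors_give_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = two_sample_t(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_matches_pooled_closed_form(self):
        x = np.array([4.1, 5.2, 6.3, 5.8])
        y = np.array([7.4, 8.1, 9.0, 8.6])
        t, p = two_sample_t(x, y, pooled=True)
        # frozen from the longhand pooled-variance formula
        assert t == pytest.approx(-4.993438317382942, abs=1e-10)
        assert p == pytest.approx(0.0024684228122780483, abs=1e-10)
        t_ref, p_ref = pooled_t_formula(x, y)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_welch_differs_under_unequal_variance(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 5, 30)
        t_pooled, _ = two_sample_t(x, y, pooled=True)
        t_welch, _ = two_sample_t(x, y, pooled=False)
        assert t_pooled != t_welch

    def test_group_swap_flips_sign(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        t_xy, p_xy = two_sample_t(x, y)
        t_yx, p_yx = two_sample_t(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_insufficient_n_is_an_error(self):
        with pytest.raises(ValueError):
            two_sample_t(np.array([1.0]), np.array([1.0, 2.0]))

    def test_zero_variance_cases(self):
        t, p = two_sample_t(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert (t, p) == (0.0, 1.0)
        t, p = two_sample_t(np.array([3.0, 3.0]), np.array([2.0, 2.0]))
        assert np.isinf(t) and t > 0 and p == 0.0


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 1])
        res = log_rank(t, e, t.copy(), e.copy())
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.direction == "none"

    def test_six_plus_six_fixture_matches_event_table(self):
        ta, ea = [1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1]
        tb, eb = [2, 3, 3, 5, 7, 8], [0, 1, 1, 1, 0, 1]
        res = log_rank(ta, ea, tb, eb)
        # frozen from the explicit per-event-time O/E/V table
        assert res.observed_a == 4.0
        assert res.expected_a == pytest.approx(3.076767676767677, abs=1e-12)
        assert res.statistic == pytest.approx(0.5190168330253843, abs=1e-12)
        assert res.p_value == pytest.approx(0.4712613745832641, abs=1e-12)
        assert res.direction == "A"
        O, E, V, stat = event_table_logrank(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(stat, abs=1e-12)

    def test_agrees_with_lifelines_on_random_data(self, rng):
        for _ in range(10):
            ta = rng.exponential(1, 20)
            tb = rng.exponential(0.5, 25)
            ea = (rng.random(20) < 0.7).astype(int)
            eb = (rng.random(25) < 0.7).astype(int)
            res = log_rank(ta, ea, tb, eb)
            ref = logrank_test(ta, tb, ea, eb)
            assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_time_rescaling_invariance(self, rng):
        ta, tb = rng.exponential(1, 15), rng.exponential(2, 15)
        ea = np.ones(15, int)
        eb = (rng.random(15) < 0.5).astype(int)
        a = log_rank(ta, ea, tb, eb)
        b = log_rank(ta * 37.5, ea, tb * 37.5, eb)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_group_relabeling_preserves_statistic_flips_direction(self, rng):
        ta, tb = rng.exponential(0.3, 12), rng.exponential(1.0, 12)
        ea = np.ones(12, int)
        eb = np.ones(12, int)
        ab = log_rank(ta, ea, tb, eb)
        ba = log_rank(tb, eb, ta, ea)
        assert ab.statistic == pytest.approx(ba.statistic, rel=1e-12)
        assert {ab.direction, ba.direction} == {"A", "B"}

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="events"):
            log_rank([1.0, 2.0], [0, 0], [1.5], [0])


class TestMedianSplit:
    def test_odd_vector(self):
        assert list(median_split([1, 2, 3])) == ["low", "low", "high"]

    def test_even_vector_with_ties(self):
        assert list(median_split([1, 1, 2, 2])) == ["low", "low", "high", "high"]

    def test_all_identical_is_an_error(self):
        with pytest.raises(ValueError):
            median_split([5.0, 5.0, 5.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100)
    def test_matches_sort_oracle_and_low_majority(self, seed):
        r = np.random.default_rng(seed)
        values = np.round(r.normal(size=int(r.integers(2, 40))), 2)
        if np.all(values == values[0]):
            return
        labels = list(median_split(values))
        assert labels == sort_based_median_split(values)
        assert labels.count("low") >= labels.count("high")


class TestFoldChangeDdct:
    def test_zero_ddct_is_unit_fold(self):
        assert fold_change_ddct(20, 18, 22, 20) == 1.0

    def test_ddct_two_is_quarter_expression(self):
        # a 2-cycle relative shift reports 25% expression
        assert fold_change_ddct(25, 20, 23, 20) == 0.25

    def test_negative_ddct_amplifies(self):
        assert fold_change_ddct(18, 20, 22, 20) == pytest.approx(16.0)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            fold_change_ddct(np.nan, 20, 23, 20)


def _toy_cohort(rng, n_genes=12, n_tumor=20, n_normal=10):
    genes = [f"GENE{i}" for i in range(n_genes)]
    tumors = [f"T{i}" for i in range(n_tumor)]
    normals = [f"N{i}" for i in range(n_normal)]
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n_tumor + n_normal)),
        index=genes, columns=tumors + normals,
    )
    group = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal,
                      index=tumors + normals)
    surv = pd.DataFrame(
        {"subject_id": tumors,
         "time": rng.exponential(1, n_tumor) + 0.01,
         "event": (rng.random(n_tumor) < 0.7).astype(int)}
    )
    return CohortData(expression=expr, group=group, survival=surv)


class TestCandidateCatalog:
    def test_identical_groups_yield_empty_catalog(self, rng):
        n = 10
        base = rng.normal(size=(6, n))
        expr = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"g{i}" for i in range(6)],
            columns=[f"T{i}" for i in range(n)] + [f"N{i}" for i in range(n)],
        )
        group = pd.Series(["tumor"] * n + ["normal"] * n, index=expr.columns)
        surv = pd.DataFrame(
            {"subject_id": [f"T{i}" for i in range(n)],
             "time": np.ones(n), "event": np.ones(n, int)}
        )
        cat = candidate_catalog(CohortData(expr, group, surv))
        assert cat.candidates == frozenset()
        assert cat.low_expr == {}

    def test_set_identity_and_size_bounds(self, rng):
        cohort = _toy_cohort(rng)
        cat = candidate_catalog(cohort, alpha=0.5)
        assert cat.candidates == frozenset(cat.low_expr) & frozenset(cat.poor_surv)
        assert len(cat.candidates) <= min(len(cat.low_expr), len(cat.poor_surv))
        assert all(p < 0.5 for p in cat.low_expr.values())
        assert all(p < 0.5 for p in cat.poor_surv.values())

    def test_degenerate_genes_are_skipped_and_listed(self, rng):
        cohort = _toy_cohort(rng, n_genes=5)
        expr = cohort.expression.copy()
        expr.loc["GENE0"] = 7.0  # zero variance everywhere
        cohort = CohortData(expr, cohort.group, cohort.survival)
        cat = candidate_catalog(cohort)
        assert "GENE0" in cat.skipped
        assert "GENE0" not in cat.low_expr and "GENE0" not in cat.poor_surv

    def test_low_expr_members_have_lower_tumor_mean(self, rng):
        cohort, _truth = simulate_cohort(
            CohortSimConfig(n_genes=60, n_planted=10, n_tumor=40, n_normal=30,
                            seed=11)
        )
        cat = candidate_catalog(cohort)
        tumor = cohort.expression[cohort.tumor_subjects]
        normal = cohort.expression[cohort.normal_subjects]
        for g in cat.low_expr:
            assert tumor.loc[g].mean() < normal.loc[g].mean()

    def test_cohort_files_roundtrip(self, rng, tmp_path):
        cohort = _toy_cohort(rng)
        paths = [tmp_path / n for n in ("e.tsv", "g.tsv", "s.tsv")]
        write_cohort(cohort, *paths)
        back = read_cohort(*paths)
        pd.testing.assert_frame_equal(
            back.expression, cohort.expression, check_names=False
        )
        assert (back.group == cohort.group).all()


class TestHomologs:
    def test_default_rule_uppercases(self):
        mapped, unmapped = map_homologs({"Atp11b"})
        assert mapped == frozenset({"ATP11B"}) and unmapped == []

    def test_empty_set(self):
        mapped, unmapped = map_homologs(set())
        assert mapped == frozenset() and unmapped == []

    def test_table_overrides_default_rule(self):
        hm = HomologMap(table={"Trp53": "TP53"})
        mapped, _ = map_homologs({"Trp53", "Atp11b"}, hm)
        assert mapped == frozenset({"TP53", "ATP11B"})

    def test_without_default_rule_unmapped_are_reported(self):
        hm = HomologMap(table={"Trp53": "TP53"}, use_default_rule=False)
        mapped, unmapped = map_homologs({"Trp53", "Atp11b"}, hm)
        assert mapped == frozenset({"TP53"}) and unmapped == ["Atp11b"]

    def test_conflicting_table_rows_rejected(self, tmp_path):
        path = tmp_path / "hm.tsv"
        path.write_text("mouse\thuman\nTrp53\tTP53\nTrp53\tTP63\n")
        with pytest.raises(ValueError, match="conflict"):
            read_homolog_map(path)

    def test_screen_vs_catalog_set_algebra(self, rng):
        cohort = _toy_cohort(rng)
        cat = candidate_catalog(cohort, alpha=0.9)
        # brute-force mapped intersection
        screen = {"Gene3", "Gene5", "Zzz"}
        mapped = {g.upper() for g in screen}
        expected = mapped & set(cat.candidates)
        assert screen_vs_catalog(screen, cat) == frozenset(expected)

    def test_screen_vs_catalog_disjoint_and_identity(self, rng):
        cohort = _toy_cohort(rng)
        cat = candidate_catalog(cohort, alpha=0.9)
        assert screen_vs_catalog({"Nope"}, cat) == frozenset()
        lower = {g.lower().capitalize() for g in cat.candidates}
        assert screen_vs_catalog(lower, cat) == cat.candidates
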