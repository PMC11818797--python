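"""Permutation test, BH-FDR, Pearson correlation, and the group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from plmnet.atlas import LOBE_GROUPS
from plmnet.stats import (bh_fdr, pearson_correlation, permutation_test,
                          run_correlations, run_group_comparison)


class TestPermutationTest:
    def test_exhaustive_hand_example(self):
        # {1,2,3} vs {10,11,12}: C(6,3)=20 assignments, |dmean|=9 attained
        # only by the observed split and its mirror -> p = 2/20.
        obs, p, n_used, exhaustive = permutation_test([1, 2, 3], [10, 11, 12],
                                                      n_perm=50_000, seed=0)
        assert exhaustive and n_used == 20
        assert obs == pytest.approx(9.0)
        assert p == pytest.approx(0.1)

    def test_sampled_close_to_exhaustive(self):
        _, p_ex, _, _ = permutation_test([1, 2, 3], [10, 11, 12],
                                         n_perm=50_000, seed=0)
        _, p_s, n_used, exhaustive = permutation_test(
            [1, 2, 3], [10, 11, 12], n_perm=19, seed=42)
        assert not exhaustive
        # sampled (50,000 draws) vs exhaustive (C(20,10) = 184,756) on the
        # same data must agree closely
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        _, p_ex2, _, ex2 = permutation_test(a, b, n_perm=200_000, seed=0)
        assert ex2
        _, p_s2, _, ex3 = permutation_test(a, b, n_perm=50_000, seed=7)
        assert not ex3
        assert abs(p_s2 - p_ex2) < 0.01

    def test_degenerate_identical_groups_give_p_one(self):
        _, p, _, _ = permutation_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0],
                                      n_perm=100, seed=0)
        assert p == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1 = permutation_test(a, b, n_perm=2000, seed=9)
        r2 = permutation_test(a, b, n_perm=2000, seed=9)
        assert r1 == r2

    def test_monte_carlo_type_one_calibration(self):
        # 2000 same-distribution replicate datasets: fraction of raw
        # p < 0.05 must sit near the nominal level.
        rng = np.random.default_rng(314)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 8))
            _, p, _, _ = permutation_test(a, b, n_perm=499,
                                          seed=int(rng.integers(2 ** 31)))
            hits += p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_null_p_values_are_valid(self):
        # P(p <= alpha) <= alpha + 1/(n_perm+1) for several alpha levels.
        rng = np.random.default_rng(99)
        n_perm, n_rep = 199, 1500
        ps = []
        for _ in range(n_rep):
            a, b = rng.normal(size=(2, 6))
            _, p, _, _ = permutation_test(a, b, n_perm=n_perm,
                                          seed=int(rng.integers(2 ** 31)))
            ps.append(p)
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            margin = 1 / (n_perm + 1) + 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
            assert np.mean(ps <= alpha) <= alpha + margin

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0], seed=0)


class TestBhFdr:
    def test_step_up_hand_example(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.20], q=0.05)
        assert np.allclose(adj, [0.05, 0.05, 0.05, 0.05, 0.20])
        assert list(rej) == [True, True, True, True, False]

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.031])
        assert adj[0] == pytest.approx(0.031)

    def test_equal_ps_are_fixed_point(self):
        adj, _ = bh_fdr([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=30))
    def test_bh_rejections_superset_of_bonferroni(self, ps):
        q = 0.05
        _, bh_rej = bh_fdr(ps, q=q)
        bonf = np.asarray(ps) <= q / len(ps)
        assert np.all(bh_rej[bonf])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2,
                    max_size=30))
    def test_adjusted_preserves_order(self, ps):
        adj, _ = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)

    def test_p_matches_t_transform_closed_form(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 20))
        r, p = pearson_correlation(x, y)
        t = r * np.sqrt(18 / (1 - r ** 2))
        p_ref = 2 * sstats.t.sf(abs(t), df=18)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _toy_lobe_table(rng, n_per_group=8, bands=("alpha",), frontal_shift=0.0):
    rows = []
    cohort_rows = []
    for g, n in (("PD", n_per_group), ("HC", n_per_group)):
        for i in range(n):
            sid = f"{g}{i:02d}"
            cohort_rows.append({"subject_id": sid, "group": g,
                                "sex": "M" if i % 2 == 0 else "F",
                                "updrs3": rng.uniform(5, 40) if g == "PD" else 0.0,
                                "disease_duration": rng.uniform(1, 10)
                                if g == "PD" else np.nan})
            for band in bands:
                for lobe in LOBE_GROUPS:
                    val = rng.normal(0.3, 0.02)
                    if lobe == "frontal" and g == "PD":
                        val += frontal_shift
                    rows.append({"subject_id": sid, "band": band,
                                 "lobe": lobe, "ec_mean": val})
    return pd.DataFrame(rows), pd.DataFrame(cohort_rows)


class TestRunGroupComparison:
    def test_planted_frontal_shift_detected_and_directional(self, rng):
        lobe, cohort = _toy_lobe_table(rng, frontal_shift=0.08)
        res = run_group_comparison(lobe, cohort, n_perm=999, seed=3)
        frontal = res[res["lobe"] == "frontal"].iloc[0]
        assert frontal["significant"] and frontal["direction"] == "PD_higher"
        assert (res["p_fdr"] >= res["p_raw"] - 1e-15).all()

    def test_one_test_per_band_lobe_cell(self, rng):
        lobe, cohort = _toy_lobe_table(rng, bands=("alpha", "beta"))
        res = run_group_comparison(lobe, cohort, n_perm=199, seed=0)
        assert len(res) == 12
        assert set(res["band"]) == {"alpha", "beta"}

    def test_subgroup_filter_restricts_sample_sizes(self, rng):
        lobe, cohort = _toy_lobe_table(rng)
        res = run_group_comparison(lobe, cohort, n_perm=199, seed=0,
                                   subgroup="male")
        assert (res["n_a"] == 4).all() and (res["n_b"] == 4).all()

    def test_empty_subgroup_rejected(self, rng):
        lobe, cohort = _toy_lobe_table(rng)
        cohort.loc[cohort["group"] == "PD", "sex"] = "M"
        lobe_f = lobe
        with pytest.raises(ValueError, match="empty"):
            run_group_comparison(lobe_f, cohort, n_perm=199, seed=0,
                                 subgroup="female")

    def test_missing_subject_rows_rejected_with_ids(self, rng):
        lobe, cohort = _toy_lobe_table(rng)
        lobe = lobe[lobe["subject_id"] != "PD00"]
        with pytest.raises(ValueError, match="PD00"):
            run_group_comparison(lobe, cohort, n_perm=199, seed=0)

    def test_planted_frontal_effect_has_smallest_raw_p(
            self, planted_pipeline_results):
        # Full-pipeline Monte-Carlo: in cohorts with the planted frontal
        # coupling increase, the frontal lobe carries the smallest raw p
        # within the carrier band in the large majority of cohorts.
        hits = 0
        for res in planted_pipeline_results:
            t = res.tests[res.tests["band"] == "alpha"]
            best = t.loc[t["p_raw"].idxmin(), "lobe"]
            hits += best == "frontal"
        assert hits >= 0.80 * len(planted_pipeline_results)

    def test_correlations_only_for_significant_cells_by_default(self, rng):
        lobe, cohort = _toy_lobe_table(rng, frontal_shift=0.08)
        res = run_group_comparison(lobe, cohort, n_perm=999, seed=3)
        corr = run_correlations(lobe, cohort, comparison=res)
        assert set(corr["lobe"]) <= set(res[res["significant"]]["lobe"])
        corr_all = run_correlations(lobe, cohort, all_pairs=True)
        assert len(corr_all) == 2 * len(LOBE_GROUPS)
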