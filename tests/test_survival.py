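"""Two-means splitting, Kaplan-Meier, log-rank, screening, intersections."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from pathstrat import (SurvivalScreen, intersect_significant, km_estimate,
                       logrank_test, screen_features, two_means_1d)
from pathstrat.exceptions import ValidationError


def brute_force_two_means(x):
    """Independent oracle: evaluate every sorted split with plain variance."""
    xs = np.sort(x)
    best, best_k = np.inf, None
    for k in range(1, len(xs)):
        wss = np.var(xs[:k]) * k + np.var(xs[k:]) * (len(xs) - k)
        if wss < best - 1e-12:
            best, best_k = wss, k
    return best, best_k


class TestTwoMeans:
    def test_obvious_split(self):
        labels = two_means_1d([1, 1, 1, 10, 10])
        np.testing.assert_array_equal(labels, [1, 1, 1, 2, 2])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            n = rng.integers(4, 51)
            x = rng.normal(size=n) * rng.uniform(0.5, 10)
            labels = two_means_1d(x)
            wss = sum(np.var(x[labels == g]) * (labels == g).sum() for g in (1, 2))
            best, _ = brute_force_two_means(x)
            assert wss == pytest.approx(best, abs=1e-8 * (1 + best))

    def test_symmetry_and_sign_flip(self):
        labels = two_means_1d([0.0, 0.0, 5.0, 5.0])
        np.testing.assert_array_equal(labels, [1, 1, 2, 2])
        flipped = two_means_1d([-0.0, -0.0, -5.0, -5.0])
        np.testing.assert_array_equal(flipped, [2, 2, 1, 1])

    def test_group_one_has_lower_mean(self, rng):
        x = rng.normal(size=30)
        labels = two_means_1d(x)
        assert x[labels == 1].mean() < x[labels == 2].mean()

    def test_constant_feature_rejected(self):
        with pytest.raises(ValidationError, match="unclusterable"):
            two_means_1d([3.0, 3.0, 3.0, 3.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            two_means_1d([1.0, 2.0, 3.0])


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        curve = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert curve(np.array([1.0, 20.0])).tolist() == [1.0, 1.0]

    def test_closed_form_no_ties(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve(0.5) == 1.0
        assert curve(2.5) == pytest.approx(1 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])

    def test_matches_lifelines_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            t = np.ceil(rng.exponential(10.0, size=n))  # integer times force ties
            e = (rng.uniform(size=n) < 0.7).astype(int)
            if e.sum() == 0:
                continue
            curve = km_estimate(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            grid = np.unique(t)
            ours = curve(grid)
            ref = kmf.predict(grid).to_numpy()
            np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestLogRank:
    def test_identical_groups_null_identity(self):
        t = np.array([3.0, 5.0, 7.0, 9.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.array([1] * 4 + [2] * 4)
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(10, 40)
        e = (rng.uniform(size=40) < 0.8).astype(int)
        g = rng.integers(1, 3, 40)
        if len(np.unique(g)) < 2:
            g[0] = 3 - g[0]
        s1, p1 = logrank_test(t, e, g)
        s2, p2 = logrank_test(t, e, 3 - g)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [1, 1], [1, 1])

    def test_matches_lifelines_on_random_censored_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            t = rng.exponential(10.0, size=n)
            if rng.uniform() < 0.5:
                t = np.ceil(t)  # tied death times
            e = (rng.uniform(size=n) < 0.7).astype(int)
            g = rng.integers(1, 3, size=n)
            if len(np.unique(g)) < 2 or e.sum() == 0:
                continue
            stat, p = logrank_test(t, e, g)
            ref = ll_logrank(t[g == 1], t[g == 2], e[g == 1], e[g == 2])
            assert stat == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)


class TestScreen:
    def test_constant_feature_skipped(self, small_cohort):
        ds = small_cohort.datasets[0]
        feats = ds.expression.data.iloc[:3].copy()
        feats.loc["FLAT"] = 5.0
        screen = SurvivalScreen().fit(feats, ds.clinical)
        assert "FLAT" not in screen.results_
        assert screen.n_skipped_ == 1

    def test_affine_rescaling_leaves_statistic(self, small_cohort):
        ds = small_cohort.datasets[0]
        feats = ds.expression.data.iloc[:5]
        a = SurvivalScreen().fit(feats, ds.clinical)
        b = SurvivalScreen().fit(feats * 3.7 + 11.0, ds.clinical)
        for f in a.results_:
            assert a.results_[f].logrank_stat == pytest.approx(
                b.results_[f].logrank_stat, rel=1e-9)

    def test_driver_pathway_significant_under_strong_hazard(self):
        from pathstrat import CohortConfig, generate_cohort, fit_all_genes, score_pathways
        hits = 0
        for seed in range(5):
            cfg = CohortConfig(n_genes=40, n_samples_per_dataset=(150,),
                               n_pathways=4, pathway_size_range=(6, 10),
                               driver_pathway_size=15, hazard_ratio=4.0,
                               state_coupling=1.0, decouple_fraction=0.0, seed=seed)
            cohort = generate_cohort(cfg)
            ds = cohort.datasets[0]
            models = fit_all_genes(ds.expression, seed=seed)
            scores = score_pathways(cohort.pathway_set, models, ds.expression)
            res = screen_features(scores.activity, ds.clinical,
                                  feature_kind="pathway_activity")
            hits += res[cohort.driver_pathway_id].p_value < 0.05
        assert hits >= 4

    def test_results_pvalues_in_unit_interval(self, small_cohort):
        ds = small_cohort.datasets[0]
        res = screen_features(ds.expression.data.iloc[:10], ds.clinical)
        for r in res.values():
            assert 0.0 < r.p_value <= 1.0
            assert r.n1 + r.n2 == len(ds.clinical)


class TestIntersect:
    def test_simple_sets(self):
        robust, pairwise = intersect_significant([{"A", "B"}, {"B", "C"}, {"B"}])
        assert robust == {"B"}
        assert pairwise[(0, 1)] == {"B"}
        assert pairwise[(0, 2)] == {"B"}

    def test_disjoint_sets_empty(self):
        robust, _ = intersect_significant([{"A"}, {"B"}, {"C"}])
        assert robust == set()

    def test_intersection_subset_of_each(self, rng):
        sets = [set(rng.choice(20, size=8, replace=False).tolist()) for _ in range(3)]
        robust, pairwise = intersect_significant(sets)
        for s in sets:
            assert robust <= s
        for pair in pairwise.values():
            assert robust <= pair
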