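import dataclasses
from itertools import product

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from hfsig.classval import (
    CentroidModel,
    auc_mann_whitney,
    draw_stratified_splits,
    evaluate_gene_set,
    fit_centroid,
    multiple_random_validation,
    predict_score,
    wilson_ci,
)
from hfsig.iolib import ValidationError
from hfsig.synthdata import simulate_bulk_cohort
from tests.conftest import make_bulk


def oracle_auc(scores, labels):
    """Pairwise-count Mann-Whitney AUC with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(p > n for p in pos for n in neg)
    ties = sum(p == n for p in pos for n in neg)
    return (2 * wins + ties) / (2 * len(pos) * len(neg))


class TestWilson:
    def test_k0_n10(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(0.2775, abs=5e-4)

    def test_k_equals_n_upper_is_one(self):
        assert wilson_ci(10, 10)[1] == 1.0

    def test_matches_statsmodels_closed_form(self):
        for n in (1, 5, 17, 60):
            for k in range(n + 1):
                lo, hi = wilson_ci(k, n)
                slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
                assert lo == pytest.approx(slo, abs=1e-12)
                assert hi == pytest.approx(shi, abs=1e-12)

    @given(st.integers(0, 50), st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_interval_contains_point_estimate(self, k, n):
        k = min(k, n)
        lo, hi = wilson_ci(k, n)
        assert lo <= k / n <= hi

    def test_n_zero_rejected(self):
        with pytest.raises(ValidationError):
            wilson_ci(0, 0)


class TestCentroid:
    def test_centroids_are_class_means(self):
        vals = np.array([[0.0, 0.0, 1.0, 1.0],
                         [0.0, 0.0, 1.0, 1.0]])
        cohort = make_bulk(vals, n_pos=2)
        model = fit_centroid(cohort, cohort.matrix.gene_ids)
        np.testing.assert_array_equal(model.centroid_positive, [0.0, 0.0])
        np.testing.assert_array_equal(model.centroid_negative, [1.0, 1.0])

    def test_duplicated_samples_same_model(self, rng):
        vals = rng.uniform(0, 3, (4, 6))
        cohort = make_bulk(vals, n_pos=3)
        doubled = make_bulk(np.hstack([vals, vals]), n_pos=0)
        doubled.labels[:] = list(cohort.labels) * 2
        m1 = fit_centroid(cohort, cohort.matrix.gene_ids)
        m2 = fit_centroid(doubled, doubled.matrix.gene_ids)
        np.testing.assert_allclose(m1.centroid_positive, m2.centroid_positive)
        np.testing.assert_allclose(m1.centroid_negative, m2.centroid_negative)

    def test_missing_feature_listed(self, rng):
        cohort = make_bulk(rng.uniform(0, 3, (3, 4)), n_pos=2)
        with pytest.raises(ValidationError, match="nope"):
            fit_centroid(cohort, ["nope"])

    def test_one_class_training_rejected(self, rng):
        cohort = make_bulk(rng.uniform(0, 3, (3, 4)), n_pos=4)
        with pytest.raises(ValidationError, match="both classes"):
            fit_centroid(cohort, cohort.matrix.gene_ids)

    def test_score_at_positive_centroid(self):
        model = CentroidModel(["g0"], np.array([2.0]), np.array([0.0]))
        assert predict_score(model, np.array([2.0])) == pytest.approx(2.0)

    def test_score_zero_at_midpoint(self):
        model = CentroidModel(["g0", "g1"], np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        assert predict_score(model, np.array([0.5, 0.5])) == pytest.approx(0.0)

    def test_score_antisymmetric_under_class_swap(self, rng):
        c1, c2 = rng.normal(size=3), rng.normal(size=3)
        x = rng.normal(size=3)
        m = CentroidModel(["a", "b", "c"], c1, c2)
        m_swapped = CentroidModel(["a", "b", "c"], c2, c1)
        assert predict_score(m, x) == pytest.approx(-predict_score(m_swapped, x))

    def test_single_feature_reduces_to_signed_distance(self, rng):
        model = CentroidModel(["g"], np.array([3.0]), np.array([1.0]))
        for x in rng.uniform(-2, 6, 20):
            expected = abs(x - 1.0) - abs(x - 3.0)
            assert predict_score(model, np.array([x])) == pytest.approx(expected)

    def test_nonfinite_input_rejected(self):
        model = CentroidModel(["g"], np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValidationError):
            predict_score(model, np.array([np.inf]))


class TestAuc:
    def test_matches_pairwise_oracle_random(self, rng):
        for _ in range(200):
            n = rng.integers(3, 12)
            scores = rng.integers(0, 4, n).astype(float)
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert auc_mann_whitney(scores, labels) == oracle_auc(scores, labels)

    def test_label_swap_maps_auc(self, rng):
        scores = rng.normal(size=20)
        labels = np.array([True] * 8 + [False] * 12)
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(scores, ~labels)
        assert a + b == pytest.approx(1.0)

    @given(st.lists(st.tuples(st.sampled_from([0.0, 0.5, 1.0, 2.0]),
                              st.booleans()), min_size=2, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_property_oracle_equivalence(self, pairs):
        scores = np.array([s for s, _ in pairs])
        labels = np.array([l for _, l in pairs])
        if labels.all() or not labels.any():
            return
        assert auc_mann_whitney(scores, labels) == oracle_auc(scores, labels)


class TestSplits:
    def test_stratification_within_one_sample(self, rng):
        y = np.array([True] * 13 + [False] * 21)
        splits = draw_stratified_splits(y, 50, 2 / 3, rng)
        overall = y.mean()
        for train, test in splits:
            assert 0 < y[train].sum() < len(train)
            frac = y[train].mean()
            # class counts preserved within +-1 sample of proportionality
            expected = overall * len(train)
            assert abs(y[train].sum() - expected) <= 1.0
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == len(y)

    def test_invalid_fraction_rejected(self, rng):
        y = np.array([True, True, False, False])
        with pytest.raises(ValidationError):
            draw_stratified_splits(y, 5, 1.0, rng)


class TestMrv:
    def test_separable_panel_gives_auc_one(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, panel_effect=5.0)
        cohort, truth = simulate_bulk_cohort(spec)
        res = multiple_random_validation(cohort, list(truth.panel),
                                         n_splits=30, seed=0)
        assert res.auc == 1.0
        assert res.sens == 1.0 and res.spec == 1.0

    def test_null_features_centered_at_half(self, tiny_spec):
        aucs = []
        for seed in range(20):
            spec = dataclasses.replace(tiny_spec, panel_effect=0.0, seed=seed)
            cohort, truth = simulate_bulk_cohort(spec)
            res = multiple_random_validation(cohort, list(truth.panel),
                                             n_splits=20, seed=seed)
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_auc_equals_oracle_on_pooled_scores(self, tiny_spec):
        cohort, truth = simulate_bulk_cohort(tiny_spec)
        res = multiple_random_validation(cohort, list(truth.panel), n_splits=15, seed=4)
        assert res.auc == oracle_auc(res.pooled_scores, res.pooled_labels)

    def test_deterministic_under_seed(self, tiny_spec):
        cohort, truth = simulate_bulk_cohort(tiny_spec)
        a = multiple_random_validation(cohort, list(truth.panel), n_splits=10, seed=9)
        b = multiple_random_validation(cohort, list(truth.panel), n_splits=10, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_roc_points_monotone_and_anchored(self, tiny_spec):
        cohort, truth = simulate_bulk_cohort(tiny_spec)
        res = multiple_random_validation(cohort, list(truth.panel), n_splits=10, seed=1)
        fpr, tpr = res.roc_points[:, 0], res.roc_points[:, 1]
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_holdout_counts_sum(self, tiny_spec):
        cohort, truth = simulate_bulk_cohort(tiny_spec)
        res = multiple_random_validation(cohort, list(truth.panel), n_splits=12, seed=2)
        assert res.holdout_count.sum() == len(res.pooled_scores)


class TestEvaluateGeneSet:
    def test_planted_panel_high_auc(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, panel_effect=3.0)
        cohort, truth = simulate_bulk_cohort(spec)
        res = evaluate_gene_set(cohort, truth.panel, n_splits=30, seed=0)
        assert res.auc >= 0.95

    def test_unmeasured_members_warned(self, tiny_spec):
        cohort, truth = simulate_bulk_cohort(tiny_spec)
        with pytest.warns(UserWarning, match="not measured"):
            res = evaluate_gene_set(cohort, list(truth.panel) + ["MISSING"],
                                    n_splits=5, seed=0)
        assert set(res.features) == set(truth.panel)

    def test_empty_intersection_rejected(self, tiny_spec):
        cohort, _ = simulate_bulk_cohort(tiny_spec)
        with pytest.raises(ValidationError, match="no gene-set member"):
            evaluate_gene_set(cohort, ["MISSING"], n_splits=5, seed=0)

    def test_null_roc_p_uniform_with_independent_scores(self, tiny_spec):
        """With one split the pooled held-out scores are independent, so the
        Welch p is uniform under the null (pooling many splits
        pseudo-replicates samples and is anti-conservative by construction —
        see decisions ledger)."""
        ps = []
        for seed in range(50):
            spec = dataclasses.replace(tiny_spec, panel_effect=0.0, seed=seed,
                                       n_bulk_samples_per_class=30)
            cohort, truth = simulate_bulk_cohort(spec)
            res = evaluate_gene_set(cohort, truth.panel, n_splits=1, seed=seed + 1)
            ps.append(res.roc_p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_same_seed_identical_result(self, tiny_spec):
        cohort, truth = simulate_bulk_cohort(tiny_spec)
        a = evaluate_gene_set(cohort, truth.panel, n_splits=8, seed=5)
        b = evaluate_gene_set(cohort, truth.panel, n_splits=8, seed=5)
        assert a.to_dict() == b.to_dict()
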