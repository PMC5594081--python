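import numpy as np
import pytest

from chronnect.ml import (
    classification_pipeline,
    distance_correlation,
    distance_correlation_matrix,
    dominant_set_clusters,
    elm_classify_loocv,
    laplacian_score,
    permutation_threshold,
    regression_pipeline,
    select_representatives,
    svr_loocv,
)


class TestDistanceCorrelation:
    def test_linear_dependence_is_one(self, rng):
        x = rng.standard_normal(100)
        assert distance_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_small(self):
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            hits += distance_correlation(r.standard_normal(500),
                                         r.standard_normal(500)) < 0.15
        assert hits >= 28

    def test_captures_nonlinearity(self):
        r = np.random.default_rng(0)
        x = r.uniform(-1, 1, 500)
        y = x**2
        assert distance_correlation(x, y) > 0.3
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.1

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            x = rng.standard_normal(60)
            y = rng.standard_normal(60) + 0.5 * x
            expected = pingouin.distance_corr(x, y, n_boot=None)
            assert distance_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_guarded(self, rng):
        assert distance_correlation(np.ones(20), rng.standard_normal(20)) == 0.0

    def test_matrix_agrees_with_pairwise(self, rng):
        F = rng.standard_normal((40, 6))
        S = distance_correlation_matrix(F)
        for i in range(6):
            for j in range(i + 1, 6):
                assert S[i, j] == pytest.approx(
                    distance_correlation(F[:, i], F[:, j]), abs=1e-10)
        assert np.allclose(np.diag(S), 0.0)


class TestDominantSets:
    def test_planted_two_blocks(self):
        S = np.full((20, 20), 0.05)
        S[:10, :10] = 0.9
        S[10:, 10:] = 0.9
        np.fill_diagonal(S, 0.0)
        clusters = dominant_set_clusters(S)
        sets = sorted([sorted(c.tolist()) for c in clusters], key=len, reverse=True)
        assert sets[0] == list(range(10)) or sets[0] == list(range(10, 20))
        assert sets[1] == list(range(10)) or sets[1] == list(range(10, 20))

    def test_no_similarity_gives_singletons(self):
        S = np.zeros((6, 6))
        clusters = dominant_set_clusters(S)
        assert len(clusters) == 6
        assert all(len(c) == 1 for c in clusters)

    def test_deterministic(self, rng):
        S = rng.uniform(0, 1, (12, 12))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0.0)
        a = dominant_set_clusters(S)
        b = dominant_set_clusters(S)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dominant_set_clusters(np.empty((0, 0)))


class TestSelectRepresentatives:
    def test_exact_age_feature_wins(self, rng):
        age = rng.uniform(18, 60, 30)
        F = np.column_stack([rng.standard_normal(30), age, rng.standard_normal(30)])
        mask = select_representatives([np.array([0, 1, 2])], F, age)
        assert mask.tolist() == [False, True, False]

    def test_one_per_cluster(self, rng):
        F = rng.standard_normal((25, 10))
        age = rng.uniform(18, 60, 25)
        partition = [np.arange(0, 4), np.arange(4, 7), np.arange(7, 10)]
        mask = select_representatives(partition, F, age)
        assert mask.sum() == 3

    def test_incomplete_partition_rejected(self, rng):
        F = rng.standard_normal((20, 5))
        with pytest.raises(ValueError):
            select_representatives([np.array([0, 1])], F, np.arange(20.0))


class TestLaplacianScore:
    def test_planted_discriminant_top_ranked(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 20)
            F = r.standard_normal((40, 30))
            F[:, 7] = y + 0.1 * r.standard_normal(40)
            scores = laplacian_score(F, y)
            hits += np.argmax(scores) == 7
        assert hits >= 19

    def test_constant_feature_zero(self, rng):
        y = np.repeat([0, 1], 10)
        F = np.column_stack([np.ones(20), rng.standard_normal(20)])
        assert laplacian_score(F, y)[0] == 0.0

    def test_scores_finite(self, rng):
        y = np.repeat([0, 1], 15)
        scores = laplacian_score(rng.standard_normal((30, 50)), y)
        assert np.isfinite(scores).all()

    def test_requires_two_groups(self, rng):
        with pytest.raises(ValueError):
            laplacian_score(rng.standard_normal((10, 3)), np.zeros(10))


class TestPermutationThreshold:
    def test_planted_features_selected(self):
        r = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        F = r.standard_normal((60, 205))
        planted = [3, 50, 100, 150, 200]
        for f in planted:
            F[:, f] = y + 0.15 * r.standard_normal(60)
        mask = permutation_threshold(F, y, n_perm=100, seed=1)
        assert all(mask[f] for f in planted)
        false_hits = mask.sum() - 5
        assert false_hits <= 10  # a few percent of 200 noise features

    def test_random_labels_select_little(self, rng):
        y = rng.permutation(np.repeat([0, 1], 25))
        F = rng.standard_normal((50, 100))
        mask = permutation_threshold(F, y, n_perm=100, seed=2)
        assert mask.mean() < 0.1

    def test_reproducible(self, rng):
        y = np.repeat([0, 1], 15)
        F = rng.standard_normal((30, 40))
        a = permutation_threshold(F, y, n_perm=60, seed=9)
        b = permutation_threshold(F, y, n_perm=60, seed=9)
        assert np.array_equal(a, b)

    def test_too_few_permutations(self, rng):
        with pytest.raises(ValueError):
            permutation_threshold(rng.standard_normal((10, 4)),
                                  np.repeat([0, 1], 5), n_perm=10)


class TestSvrLoocv:
    def test_linear_recovery(self):
        r = np.random.default_rng(4)
        age = r.uniform(18, 60, 40)
        F = np.column_stack([age + 0.5 * r.standard_normal(40) for _ in range(3)]
                            + [r.standard_normal(40) for _ in range(5)])
        res = svr_loocv(F, age)
        assert res.r2 > 0.9
        assert 0.8 <= res.slope <= 1.1
        assert len(res.predictions) == 40

    def test_noiseless_near_perfect(self, rng):
        age = rng.uniform(20, 50, 30)
        F = np.column_stack([age, 2 * age + 1])
        res = svr_loocv(F, age)
        assert res.r2 > 0.99

    def test_summary_mentions_r2(self, rng):
        age = rng.uniform(20, 50, 15)
        res = svr_loocv(np.column_stack([age]), age)
        assert "R^2" in res.summary()

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            svr_loocv(rng.standard_normal((5, 2)), rng.uniform(18, 60, 5))

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError):
            svr_loocv(rng.standard_normal((12, 2)), np.full(12, 30.0))


class TestElm:
    def test_separable_classes_perfect(self):
        r = np.random.default_rng(1)
        X = np.vstack([r.standard_normal((50, 2)) + [4, 4],
                       r.standard_normal((50, 2)) - [4, 4]])
        y = np.repeat(["a", "b"], 50)
        res = elm_classify_loocv(X, y, n_hidden=100, seed=0)
        assert res.accuracy == 100.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_shuffled_labels_chance(self):
        r = np.random.default_rng(2)
        X = r.standard_normal((100, 5))
        y = r.permutation(np.repeat(["a", "b"], 50))
        res = elm_classify_loocv(X, y, n_hidden=50, seed=0)
        assert 30.0 <= res.accuracy <= 70.0

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.repeat(["a", "b"], 15)
        r1 = elm_classify_loocv(X, y, seed=5)
        r2 = elm_classify_loocv(X, y, seed=5)
        assert np.array_equal(r1.predictions, r2.predictions)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            elm_classify_loocv(rng.standard_normal((10, 2)), np.zeros(10))


class TestPipelines:
    def test_nested_regression_recovers_planted_effect(self):
        from chronnect.synthgen import gen_feature_cohort

        F, ages, _ = gen_feature_cohort(n_subjects=50, n_noise=10, seed=3)
        res = regression_pipeline(F, ages, nested=True)
        assert res.r2 > 0.9

    def test_nested_null_guard(self):
        """Shuffled ages cannot leak through nested selection."""
        from chronnect.synthgen import gen_feature_cohort

        F, ages, _ = gen_feature_cohort(n_subjects=40, n_noise=10, seed=5)
        shuffled = np.random.default_rng(0).permutation(ages)
        res = regression_pipeline(F, shuffled, nested=True)
        assert res.r2 <= 0.1

    def test_classification_pipeline_runs(self):
        from chronnect.synthgen import gen_feature_cohort

        F, ages, groups = gen_feature_cohort(n_subjects=40, n_noise=10, seed=7)
        res = classification_pipeline(F, groups, nested=False, n_perm=60, seed=0)
        assert 0.0 <= res.accuracy <= 100.0
        assert res.selected
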