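import numpy as np
import pytest
from scipy.stats import chi2_contingency

from gsikit import (
    GenotypeMatrix,
    SimParams,
    TuningGrid,
    apply_introgression,
    chi_square_independence,
    classification_metrics,
    confusion_table,
    default_forest_grid,
    default_grids,
    draw_population_frequencies,
    enumerate_grid,
    impute_means,
    loocv_evaluate,
    predict_membership,
    probability_distribution_summary,
    simulate_genotypes,
    stratified_split,
    train_fixed,
    tune_and_train,
)

M = np.nan


def labelled_gm(dosage, labels):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(dosage.shape[0])],
        marker_ids=[f"m{j}" for j in range(dosage.shape[1])],
        dosage=dosage,
        labels=list(labels),
    )


def two_pop_gm(F, n_snps, n_per_pop, seed, maf=(0.05, 0.5)):
    params = SimParams(n_snps=n_snps, divergence_F=F, n_per_pop=n_per_pop,
                       ancestral_maf_range=maf, seed=seed)
    return simulate_genotypes(draw_population_frequencies(params), params)


class TestImputeMeans:
    def test_missing_becomes_observed_mean(self):
        X = np.array([[0.0], [2.0], [M], [2.0]])
        out, means = impute_means(X)
        assert out[2, 0] == pytest.approx(4 / 3)
        assert means[0] == pytest.approx(4 / 3)

    def test_no_missing_identity(self):
        X = np.array([[0.0, 1.0], [2.0, 1.0]])
        out, _ = impute_means(X)
        np.testing.assert_array_equal(out, X)

    def test_output_within_dosage_scale(self, rng):
        X = rng.integers(0, 3, size=(50, 10)).astype(float)
        X[rng.random(X.shape) < 0.2] = M
        out, _ = impute_means(X)
        assert not np.isnan(out).any()
        assert out.min() >= 0.0 and out.max() <= 2.0

    def test_stored_means_reused_at_prediction(self):
        train = np.array([[0.0], [2.0]])
        _, means = impute_means(train)
        test = np.array([[M]])
        out, _ = impute_means(test, means)
        assert out[0, 0] == 1.0

    def test_all_missing_marker_rejected(self):
        with pytest.raises(ValueError, match="QC"):
            impute_means(np.array([[M], [M]]))


class TestStratifiedSplit:
    def test_study_split_sizes(self):
        """100 target + 91 other at 20%: test 20 + 18 = 38, train 80 + 73."""
        labels = ["RHB"] * 100 + ["other"] * 91
        train, test = stratified_split(labels, 0.20, seed=3)
        assert len(test) == 38 and len(train) == 153
        test_labels = [labels[i] for i in test]
        assert test_labels.count("RHB") == 20
        assert test_labels.count("other") == 18

    def test_zero_fraction_empty_test(self):
        train, test = stratified_split(["a"] * 5 + ["b"] * 5, 0.0, seed=0)
        assert len(test) == 0 and len(train) == 10

    def test_seed_determinism(self):
        labels = ["a"] * 30 + ["b"] * 30
        t1 = stratified_split(labels, 0.2, seed=7)
        t2 = stratified_split(labels, 0.2, seed=7)
        t3 = stratified_split(labels, 0.2, seed=8)
        np.testing.assert_array_equal(t1[1], t2[1])
        assert not np.array_equal(t1[1], t3[1])


class TestGridEnumeration:
    def test_published_grid_has_162_combinations(self):
        combos = enumerate_grid(default_forest_grid())
        assert len(combos) == 162
        assert combos[0] == {"mtry": 2, "splitrule": "gini", "min_node_size": 2}

    def test_single_value_lists(self):
        grid = TuningGrid("knn", {"k": [5]})
        assert enumerate_grid(grid) == [{"k": 5}]

    def test_matches_nested_loop_oracle(self):
        grid = TuningGrid("x", {"a": [1, 2], "b": ["u", "v", "w"]})
        combos = enumerate_grid(grid)
        expected = [{"a": a, "b": b} for a in (1, 2) for b in ("u", "v", "w")]
        assert combos == expected


class TestLoocv:
    def test_separable_data_perfect_f_score(self):
        gm = two_pop_gm(F=0.4, n_snps=30, n_per_pop=20, seed=31,
                        maf=(0.3, 0.5))
        m = loocv_evaluate(gm.dosage, gm.labels, "random_forest",
                           {"mtry": 3, "splitrule": "gini", "min_node_size": 2},
                           positive_class="pop0", seed=0, n_trees=50)
        assert m["f_score"] == pytest.approx(1.0)
        assert m["accuracy"] == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self, rng):
        gm = two_pop_gm(F=0.3, n_snps=20, n_per_pop=15, seed=32)
        labels = list(gm.labels)
        rng.shuffle(labels)
        m = loocv_evaluate(gm.dosage, labels, "knn", {"k": 3},
                           positive_class="pop0", seed=0)
        assert 0.2 <= m["accuracy"] <= 0.8

    def test_minimum_size_runs(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0], [0.0, 1.0]])
        m = loocv_evaluate(X, ["a", "b", "a"], "knn", {"k": 1},
                           positive_class="a", seed=0)
        assert set(m) == {"f_score", "accuracy", "kappa"}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            loocv_evaluate(np.zeros((2, 2)), ["a", "b"], "knn", {"k": 1},
                           positive_class="a")


class TestTuneAndTrain:
    def test_leaderboard_covers_all_combinations(self):
        gm = two_pop_gm(F=0.4, n_snps=10, n_per_pop=6, seed=33)
        grids = [TuningGrid("knn", {"k": [1, 3]}),
                 TuningGrid("naive_bayes", {"var_smoothing": [1e-9]})]
        _, board = tune_and_train(gm, grids, "pop0", seed=0)
        assert len(board) == 3

    def test_deterministic_winner(self):
        gm = two_pop_gm(F=0.3, n_snps=12, n_per_pop=8, seed=34)
        grids = default_grids(small=True)
        m1, _ = tune_and_train(gm, grids, "pop0", seed=1, n_trees=25)
        m2, _ = tune_and_train(gm, grids, "pop0", seed=1, n_trees=25)
        assert (m1.algorithm, m1.params) == (m2.algorithm, m2.params)

    def test_unlabelled_matrix_rejected(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["m"], np.zeros((3, 1)))
        with pytest.raises(ValueError, match="labels"):
            tune_and_train(gm, [TuningGrid("knn", {"k": [1]})], "x")


class TestPredictMembership:
    def _fitted(self, seed=35):
        gm = two_pop_gm(F=0.4, n_snps=30, n_per_pop=25, seed=seed,
                        maf=(0.3, 0.5))
        model = train_fixed(gm, "random_forest",
                            {"mtry": 3, "splitrule": "extratrees",
                             "min_node_size": 2},
                            positive_class="pop0", seed=0, n_trees=100)
        return model, gm

    def test_training_samples_on_correct_side(self):
        model, gm = self._fitted()
        proba, labels = predict_membership(model, gm)
        truth = np.asarray(gm.labels) == "pop0"
        assert ((proba > 0.5) == truth).mean() > 0.97
        assert ((np.asarray(labels) == "pop0") == (proba > 0.5)).all()

    def test_probability_exactly_half_goes_to_other_class(self):
        model, gm = self._fitted()
        classes = list(model.estimator.classes_)

        class Half:
            classes_ = model.estimator.classes_

            def predict_proba(self, X):
                return np.full((len(X), len(classes)), 0.5)

        model.estimator = Half()
        _, labels = predict_membership(model, gm, threshold=0.5)
        assert all(l != "pop0" for l in labels)

    def test_probabilities_bounded(self):
        model, gm = self._fitted(seed=36)
        proba, _ = predict_membership(model, gm)
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_marker_mismatch_explicit_error(self):
        model, gm = self._fitted()
        bad = gm.subset_markers(gm.marker_ids[:-1])
        with pytest.raises(ValueError, match="snp29"):
            predict_membership(model, bad)


class TestMetrics:
    def test_study_confusion_matrix_values(self):
        """[[14,6],[6,12]]: accuracy 26/38 = 0.6842, F = 0.7000, and the
        marginal-based kappa evaluates to 0.3667."""
        known = ["R"] * 20 + ["O"] * 18
        pred = ["R"] * 14 + ["O"] * 6 + ["R"] * 6 + ["O"] * 12
        rep = classification_metrics(known, pred, "R")
        np.testing.assert_array_equal(rep.confusion, [[14, 6], [6, 12]])
        assert rep.accuracy == pytest.approx(0.6842, abs=5e-5)
        assert rep.f_score == pytest.approx(0.7000, abs=5e-5)
        assert rep.kappa == pytest.approx(0.3667, abs=5e-5)

    def test_perfect_prediction(self):
        known = pred = ["a", "b", "a", "b"]
        rep = classification_metrics(known, pred, "a")
        assert rep.accuracy == rep.f_score == rep.kappa == 1.0

    def test_no_positive_predictions_flagged(self):
        rep = classification_metrics(["a", "b"], ["b", "b"], "a")
        assert rep.undefined_precision
        assert rep.f_score == 0.0

    def test_class_swap_exchanges_sensitivity_specificity(self, rng):
        known = rng.choice(["a", "b"], size=60).tolist()
        pred = rng.choice(["a", "b"], size=60).tolist()
        ra = classification_metrics(known, pred, "a")
        rb = classification_metrics(known, pred, "b")
        assert ra.sensitivity == pytest.approx(rb.specificity)
        assert ra.specificity == pytest.approx(rb.sensitivity)
        assert ra.accuracy == pytest.approx(rb.accuracy)
        assert ra.kappa == pytest.approx(rb.kappa)


class TestChiSquare:
    def test_study_tables(self):
        stat, df, p = chi_square_independence(np.array([[14, 6], [6, 12]]))
        assert stat == pytest.approx(3.744, abs=5e-4)
        assert df == 1 and p == pytest.approx(0.053, abs=5e-4)
        stat2, _, p2 = chi_square_independence(np.array([[20, 0], [0, 18]]))
        assert stat2 == pytest.approx(34.095, abs=5e-4)
        assert p2 == pytest.approx(5.25e-9, rel=5e-3)

    def test_independent_margins_near_zero(self):
        stat, _, _ = chi_square_independence(np.array([[30, 30], [30, 30]]))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_flagged(self):
        stat, _, p = chi_square_independence(np.array([[5, 5], [0, 0]]))
        assert np.isnan(stat) and np.isnan(p)

    def test_uncorrected_matches_scipy_oracle(self, rng):
        for _ in range(20):
            t = rng.integers(1, 40, size=(2, 2))
            ours, _, pours = chi_square_independence(t, correction=False)
            ref = chi2_contingency(t, correction=False)
            assert ours == pytest.approx(ref.statistic, abs=1e-10)
            assert pours == pytest.approx(ref.pvalue, abs=1e-10)


class TestProbabilitySummary:
    def test_single_value_collapses(self):
        s = probability_distribution_summary({"g": [0.4]})["g"]
        assert set(s.values()) == {0.4}

    def test_symmetric_three_points(self):
        s = probability_distribution_summary({"g": [0.0, 0.5, 1.0]})["g"]
        assert s["median"] == 0.5 and s["mean"] == 0.5

    def test_matches_sort_oracle(self, rng):
        v = rng.random(37)
        s = probability_distribution_summary({"g": v})["g"]
        srt = np.sort(v)
        assert s["min"] == srt[0] and s["max"] == srt[-1]
        assert s["median"] == pytest.approx(np.quantile(srt, 0.5))
        assert s["q1"] == pytest.approx(np.quantile(srt, 0.25))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            probability_distribution_summary({"g": []})


class TestEndToEndClassification:
    def test_heldout_accuracy_at_study_divergence(self):
        """Two stocks at F = 0.1 with 81 markers and 80 training samples per
        class: held-out assignment accuracy >= 0.95 across seeds."""
        accs = []
        for seed in range(5):
            gm = two_pop_gm(F=0.1, n_snps=81, n_per_pop=100, seed=40 + seed)
            train_idx, test_idx = stratified_split(gm.labels, 0.20, seed=seed)
            train = gm.subset_samples([gm.sample_ids[i] for i in train_idx])
            test = gm.subset_samples([gm.sample_ids[i] for i in test_idx])
            model = train_fixed(
                train, "random_forest",
                {"mtry": 5, "splitrule": "extratrees", "min_node_size": 3},
                positive_class="pop0", seed=seed, n_trees=500,
            )
            _, pred = predict_membership(model, test)
            accs.append((np.asarray(pred) == np.asarray(test.labels)).mean())
        assert np.mean(accs) >= 0.95

    def test_membership_probability_decreases_with_introgression(self):
        """Mean predicted target-stock membership of admixed samples is
        non-increasing in the admixture proportion alpha."""
        params = SimParams(n_snps=81, divergence_F=0.115, n_per_pop=80, seed=50)
        freqs = draw_population_frequencies(params)
        train = simulate_genotypes(freqs, params)
        model = train_fixed(
            train, "random_forest",
            {"mtry": 5, "splitrule": "extratrees", "min_node_size": 3},
            positive_class="pop0", seed=0, n_trees=300,
        )
        means = []
        for k, alpha in enumerate((0.0, 0.25, 0.5)):
            shifted = freqs.copy()
            shifted[:, 0] = apply_introgression(freqs[:, 0], freqs[:, 1], alpha)
            novel = simulate_genotypes(
                shifted, params.with_(seed=60 + k, n_per_pop=60)
            )
            target = novel.subset_samples(
                [s for s, l in zip(novel.sample_ids, novel.labels)
                 if l == "pop0"]
            )
            proba, _ = predict_membership(model, target)
            means.append(proba.mean())
        assert means[0] > means[1] > means[2]
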