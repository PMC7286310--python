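"""Unit tests for vectorization, cross-validated classification, RFE
biomarkers, dimensionality-reduction diagnostics and link-wise testing."""

import numpy as np
import pytest

from mouec import (
    CohortSample,
    chance_level,
    classify_cv,
    data_to_parameter_ratio,
    linkwise_tests,
    reduce_and_silhouette,
    rfe_biomarker,
    scatter_features,
    split_collision_probability,
    vectorize_connectivity,
)
from mouec.ml import _run_split, make_splits


def make_cohort_samples(
    n_subjects=10,
    sessions_per_condition={"rest": 2, "movie": 3},
    n_features=40,
    shift_links=(),
    shift=0.0,
    subject_offset_sd=0.0,
    seed=0,
):
    """Synthetic feature cohort: iid normal features, a per-condition mean
    shift on selected links, and optional per-subject offsets."""
    rng = np.random.default_rng(seed)
    samples = []
    for s in range(n_subjects):
        offset = subject_offset_sd * rng.standard_normal(n_features)
        for cond, n_sess in sessions_per_condition.items():
            for k in range(n_sess):
                x = rng.standard_normal(n_features) + offset
                if cond != "rest" and shift:
                    x[list(shift_links)] += shift
                samples.append(
                    CohortSample(
                        features=x,
                        subject_id=f"sub-{s:02d}",
                        condition=cond,
                        session_id=f"sub-{s:02d}_{cond}-{k}",
                    )
                )
    return samples


class TestVectorization:
    def test_mask_order_row_major(self):
        mat = np.arange(9.0).reshape(3, 3)
        mask = np.zeros((3, 3), dtype=int)
        mask[0, 1] = mask[2, 0] = 1
        vec, idx = vectorize_connectivity(mat, mask)
        np.testing.assert_array_equal(vec, [mat[0, 1], mat[2, 0]])
        assert idx == [(0, 1), (2, 0)]

    def test_fc_mode_upper_triangle_length(self):
        vec, idx = vectorize_connectivity(np.eye(4), "fc")
        assert len(vec) == 6
        assert all(i < j for i, j in idx)

    def test_round_trip_restores_masked_entries(self):
        rng = np.random.default_rng(2)
        mat = rng.random((5, 5))
        mask = (rng.random((5, 5)) < 0.4).astype(int)
        np.fill_diagonal(mask, 0)
        vec, idx = vectorize_connectivity(mat, mask)
        restored = scatter_features(vec, idx, 5)
        np.testing.assert_array_equal(restored[mask.astype(bool)],
                                      mat[mask.astype(bool)])
        assert np.all(restored[~mask.astype(bool)] == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mask shape"):
            vectorize_connectivity(np.eye(4), np.zeros((3, 3)))


class TestClassification:
    def test_separable_cohort_perfect_mlr(self):
        samples = make_cohort_samples(shift_links=range(10), shift=5.0)
        res = classify_cv(samples, "condition", "mlr", n_splits=10, seed=0)
        assert res.mean_accuracy == 1.0

    def test_shuffled_labels_at_chance(self):
        samples = make_cohort_samples(shift_links=range(10), shift=5.0, seed=3)
        rng = np.random.default_rng(7)
        conditions = [s.condition for s in samples]
        # shuffle condition labels within subjects so groups stay valid
        shuffled = list(conditions)
        rng.shuffle(shuffled)
        for s, c in zip(samples, shuffled):
            s.condition = c
        res = classify_cv(samples, "condition", "mlr", n_splits=40, seed=0)
        # permuted labels give label-agreement accuracy (~0.52) up to the
        # 0.6 majority chance; compare on the across-split spread
        sd = res.accuracies.std(ddof=1)
        assert abs(res.mean_accuracy - res.chance_level) < max(3 * sd, 0.15)

    def test_chance_level_three_movie_two_rest(self):
        samples = make_cohort_samples()
        labels = np.array([s.condition for s in samples])
        assert chance_level(labels) == pytest.approx(0.6)

    def test_group_integrity_no_subject_straddles_split(self):
        samples = make_cohort_samples()
        splits = make_splits(samples, "condition", "shuffle80_20", 20, seed=1)
        subjects = np.array([s.subject_id for s in samples])
        for train, test in splits:
            assert not set(subjects[train]) & set(subjects[test])

    def test_leave_one_subject_out_split_count(self):
        samples = make_cohort_samples(shift_links=range(10), shift=5.0)
        res = classify_cv(samples, "condition", "mlr",
                          scheme="leave_one_subject_out", seed=0)
        assert res.n_splits == 10  # one fold per subject

    def test_subject_identification_splits_within_subject(self):
        samples = make_cohort_samples(subject_offset_sd=5.0)
        splits = make_splits(samples, "subject", "shuffle80_20", 5, seed=0)
        subjects = np.array([s.subject_id for s in samples])
        for train, test in splits:
            # every subject appears on both sides
            assert set(subjects[train]) == set(subjects[test])
        res = classify_cv(samples, "subject", "mlr", n_splits=5, seed=0)
        assert res.mean_accuracy > 0.9

    def test_identical_seed_reproducible(self):
        samples = make_cohort_samples(shift_links=range(5), shift=1.0)
        a = classify_cv(samples, "condition", "knn", n_splits=10, seed=5)
        b = classify_cv(samples, "condition", "knn", n_splits=10, seed=5)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_confusion_row_sums_match_test_counts(self):
        samples = make_cohort_samples(shift_links=range(10), shift=2.0)
        res = classify_cv(samples, "condition", "lda", n_splits=10, seed=0)
        # 2 test subjects per split, 10 splits: 20 rest and 30 movie tested
        assert res.confusion.sum() == 10 * 2 * 5
        assert res.confusion[res.classes.index("rest")].sum() == 10 * 2 * 2

    def test_standardization_fitted_on_train_only(self):
        # sentinel: an extreme outlier in the test fold must not change the
        # predictions for the other test samples
        samples = make_cohort_samples(shift_links=range(10), shift=2.0)
        x = np.vstack([s.features for s in samples])
        y = np.array([s.condition for s in samples])
        train = np.arange(0, 40)
        test = np.arange(40, 50)
        baseline = _run_split(x, y, train, test, "mlr", standardize=True)
        x_out = x.copy()
        x_out[test[0]] += 1e6
        poisoned = _run_split(x_out, y, train, test, "mlr", standardize=True)
        np.testing.assert_array_equal(baseline[1:], poisoned[1:])


class TestRFE:
    def test_planted_links_ranked_on_top(self):
        samples = make_cohort_samples(
            n_features=100, shift_links=range(5), shift=3.0, seed=1
        )
        ranking = rfe_biomarker(samples, "condition", n_splits=5, seed=0)
        assert set(np.nonzero(ranking.rank <= 10)[0]) >= set(range(5))

    def test_rank_is_permutation(self):
        samples = make_cohort_samples(n_features=30, shift_links=range(3),
                                      shift=2.0)
        ranking = rfe_biomarker(samples, "condition", n_splits=5, seed=0)
        assert sorted(ranking.rank) == list(range(1, 31))

    def test_full_set_accuracy_matches_classify_cv(self):
        samples = make_cohort_samples(shift_links=range(5), shift=1.5, seed=2)
        ranking = rfe_biomarker(samples, "condition", n_splits=8, seed=3)
        full = dict(ranking.accuracy_curve)[len(samples[0].features)]
        res = classify_cv(samples, "condition", "mlr", n_splits=8, seed=3)
        assert full == pytest.approx(res.mean_accuracy)

    def test_support_at_accuracy_maximum(self):
        samples = make_cohort_samples(n_features=50, shift_links=range(5),
                                      shift=3.0)
        ranking = rfe_biomarker(samples, "condition", n_splits=5, seed=0)
        best_acc = max(acc for _, acc in ranking.accuracy_curve)
        sizes_at_best = [n for n, acc in ranking.accuracy_curve
                         if acc >= best_acc - 1e-12]
        assert ranking.support.sum() == min(sizes_at_best)

    def test_nested_contrasts_share_support(self):
        # links separating rest vs movie are a subset of those separating
        # four conditions; their supports should overlap substantially
        rng = np.random.default_rng(4)
        samples = []
        shared = list(range(6))
        extras = {"m1": [], "m2": list(range(6, 10)), "m3": list(range(10, 14))}
        for s in range(10):
            for cond, n_sess in [("rest", 2), ("m1", 1), ("m2", 1), ("m3", 1)]:
                for k in range(n_sess):
                    x = rng.standard_normal(60)
                    if cond != "rest":
                        x[shared] += 3.0
                        x[extras[cond]] += 3.0
                    samples.append(CohortSample(
                        features=x, subject_id=f"sub-{s:02d}", condition=cond))
        coarse = [CohortSample(
            features=s.features, subject_id=s.subject_id,
            condition="rest" if s.condition == "rest" else "movie")
            for s in samples]
        rank_coarse = rfe_biomarker(coarse, "condition", n_splits=5, seed=0)
        rank_fine = rfe_biomarker(samples, "condition", n_splits=5, seed=0)
        overlap = (rank_coarse.support & rank_fine.support).sum()
        assert overlap >= 0.5 * rank_coarse.support.sum()


class TestDimensionalityReduction:
    def test_separated_blobs_high_silhouette(self):
        samples = make_cohort_samples(shift_links=range(20), shift=8.0)
        _, sil = reduce_and_silhouette(samples, "pca", 2, "condition")
        assert sil > 0.9

    def test_random_split_of_one_blob_near_zero(self):
        samples = make_cohort_samples(seed=6)  # no condition effect at all
        _, sil = reduce_and_silhouette(samples, "pca", 2, "condition")
        assert abs(sil) < 0.2

    def test_pca_component_variances_non_increasing(self):
        samples = make_cohort_samples(shift_links=range(5), shift=2.0)
        coords, _ = reduce_and_silhouette(samples, "pca", 4, "condition")
        variances = coords.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-10)

    def test_lda_needs_two_samples_per_class(self):
        samples = make_cohort_samples(n_subjects=1,
                                      sessions_per_condition={"rest": 1,
                                                              "movie": 3})
        with pytest.raises(ValueError, match="2 samples"):
            reduce_and_silhouette(samples, "lda", 1, "condition")


class TestLinkwiseTests:
    def test_null_rejection_rate_controlled(self):
        samples = make_cohort_samples(n_features=200, seed=11)
        res = linkwise_tests(samples, alpha=0.05)
        assert res.bh_rejections.mean() <= 0.05

    def test_planted_shift_passes_bonferroni(self):
        samples = make_cohort_samples(
            n_subjects=8, n_features=200, shift_links=range(10), shift=3.0,
            sessions_per_condition={"rest": 3, "movie": 3}, seed=12,
        )
        res = linkwise_tests(samples, alpha=0.05)
        assert np.all(res.p_values[:10] < res.bonferroni_threshold)

    def test_bonferroni_log_threshold_for_paper_scale(self):
        samples = make_cohort_samples(n_features=100, seed=1)
        res = linkwise_tests(samples, alpha=0.05)
        assert res.bonferroni_threshold == pytest.approx(0.05 / 100)
        # at the reference feature count the log10 threshold is ~4.37
        assert -np.log10(0.05 / 1180) == pytest.approx(4.373, abs=5e-4)

    def test_bh_rejections_monotone_in_alpha(self):
        samples = make_cohort_samples(
            n_features=100, shift_links=range(10), shift=1.0, seed=13
        )
        strict = linkwise_tests(samples, alpha=0.01)
        loose = linkwise_tests(samples, alpha=0.05)
        assert np.all(loose.bh_rejections[strict.bh_rejections])

    def test_multiclass_takes_minimum_over_pairs(self):
        rng = np.random.default_rng(14)
        samples = []
        for s in range(6):
            for cond in ("a", "b", "c"):
                for k in range(2):
                    x = rng.standard_normal(5)
                    if cond == "c":
                        x[0] += 4.0
                    samples.append(CohortSample(features=x,
                                                subject_id=f"s{s}",
                                                condition=cond))
        res = linkwise_tests(samples)
        assert res.n_pairs_tested == 3
        assert res.p_values[0] < 1e-3

    def test_constant_feature_rejected(self):
        samples = make_cohort_samples(n_features=5)
        for s in samples:
            s.features = s.features.copy()
            s.features[2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            linkwise_tests(samples)

    def test_welch_alternative_agrees_on_strong_effect(self):
        samples = make_cohort_samples(
            n_features=20, shift_links=range(3), shift=4.0, seed=15
        )
        mw = linkwise_tests(samples, test="mannwhitneyu")
        welch = linkwise_tests(samples, test="welch")
        np.testing.assert_array_equal(mw.bh_rejections[:3], welch.bh_rejections[:3])


class TestStudyDesignArithmetic:
    def test_birthday_collision_for_reference_design(self):
        # 100 draws of 4-of-22 test sets: collision chance just below 50%
        p = split_collision_probability(22, 4, 100)
        assert 0.45 <= p <= 0.50

    def test_data_to_parameter_ratio_reference(self):
        assert data_to_parameter_ratio(66, 300, 1180) == 16

    def test_collision_probability_monotone_in_repeats(self):
        p50 = split_collision_probability(22, 4, 50)
        p100 = split_collision_probability(22, 4, 100)
        assert 0 < p50 < p100 < 1
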