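import numpy as np
import pytest

from microresp import (
    MultiTrialSVC,
    draw_balanced,
    run_cv_trial,
    run_trials,
)


def separable_composition(n_per_class=25, seed=0):
    """Two-taxon compositional data with a huge class gap (separable limit)."""
    rng = np.random.default_rng(seed)
    a = 0.9 + rng.normal(0, 0.01, n_per_class)
    b = 0.1 + rng.normal(0, 0.01, n_per_class)
    top = np.column_stack([a, 1 - a])
    bot = np.column_stack([b, 1 - b])
    X = np.clip(np.vstack([top, bot]), 1e-6, None)
    X /= X.sum(axis=1, keepdims=True)
    d = np.repeat([1, -1], n_per_class)
    return X, d


class TestDrawBalanced:
    def test_study_geometry(self, default_cohort):
        rng = np.random.default_rng(0)
        draw = draw_balanced(default_cohort.d, rng)
        assert draw.pos_pool.size == 20 and draw.neg_pool.size == 20
        assert len(draw.folds) == 5
        for fold in draw.folds:
            assert fold.size == 8
            assert (default_cohort.d[fold] == 1).sum() == 4
            assert (default_cohort.d[fold] == -1).sum() == 4
        train_size = draw.pool.size - draw.folds[0].size
        assert train_size == 32
        # folds partition the pool
        assert sorted(np.concatenate(draw.folds)) == sorted(draw.pool)

    def test_exhausted_class_used_every_draw(self, default_cohort):
        d = default_cohort.d
        draws = [
            draw_balanced(d, np.random.default_rng(s)) for s in (1, 2)
        ]
        neg_sets = [set(dr.neg_pool.tolist()) for dr in draws]
        assert neg_sets[0] == neg_sets[1] == set(np.flatnonzero(d == -1).tolist())
        # the oversampled class differs between seeds (pigeonhole on 76 choose 20)
        assert set(draws[0].pos_pool.tolist()) != set(draws[1].pos_pool.tolist())

    def test_class_too_small(self):
        d = np.array([1] * 30 + [-1] * 10)
        with pytest.raises(ValueError, match="only 10 samples"):
            draw_balanced(d, np.random.default_rng(0))
        # a smaller configurable pool makes the same labels drawable
        draw = draw_balanced(d, np.random.default_rng(0), pool_per_class=10)
        assert draw.pool.size == 20

    def test_pool_fold_divisibility(self):
        d = np.repeat([1, -1], 30)
        with pytest.raises(ValueError, match="divisible"):
            draw_balanced(d, np.random.default_rng(0), pool_per_class=21)

    def test_grouped_mode_keeps_subjects_whole(self, default_cohort):
        subj = default_cohort.table.subjects.to_numpy()
        draw = draw_balanced(
            default_cohort.d, np.random.default_rng(3), subject_of=subj
        )
        for fold in draw.folds:
            members = subj[fold]
            for s in np.unique(members):
                assert (members == s).sum() == 4  # whole subjects only


class TestRunCvTrial:
    def test_separable_limit_all_folds_perfect(self):
        X, d = separable_composition()
        draw = draw_balanced(d, np.random.default_rng(1))
        accs, models = run_cv_trial(X, d, None, draw, C=10.0)
        np.testing.assert_array_equal(accs, 1.0)
        assert len(models) == 5

    def test_accuracy_granularity_eighths(self, default_cohort):
        draw = draw_balanced(default_cohort.d, np.random.default_rng(2))
        accs, _ = run_cv_trial(
            default_cohort.X, default_cohort.d, default_cohort.s1, draw
        )
        np.testing.assert_allclose(accs * 8, np.round(accs * 8), atol=1e-12)


class TestRunTrials:
    def test_single_trial_counts(self, default_cohort):
        report, avg = run_trials(
            default_cohort.X, default_cohort.d, default_cohort.s1, T=1, seed=0
        )
        assert report.fold_acc.shape == (1, 5)
        assert len(report.models) == 5
        assert avg.n_models == 5
        assert avg.w_star.shape == (default_cohort.s1.size,)

    def test_determinism_and_seed_sensitivity(self, default_cohort):
        args = (default_cohort.X, default_cohort.d, default_cohort.s1)
        r1, a1 = run_trials(*args, T=3, seed=42)
        r2, a2 = run_trials(*args, T=3, seed=42)
        np.testing.assert_array_equal(r1.fold_acc, r2.fold_acc)
        np.testing.assert_array_equal(a1.w_star, a2.w_star)
        r3, _ = run_trials(*args, T=3, seed=43)
        assert not np.array_equal(r1.fold_acc, r3.fold_acc)

    def test_chance_level_with_independent_labels(self):
        rng = np.random.default_rng(9)
        X = rng.dirichlet(np.ones(10), size=60)
        d = np.repeat([1, -1], 30)  # labels independent of features
        report, _ = run_trials(X, d, None, T=30, seed=5)
        se = report.sd / np.sqrt(report.T)
        assert abs(report.mean - 0.5) < max(3 * se, 0.06)

    def test_averaged_model_stabilizes_with_T(self, strong_cohort):
        args = (strong_cohort.X, strong_cohort.d, strong_cohort.s1)
        _, a_small = run_trials(*args, T=15, seed=1)
        _, a_big = run_trials(*args, T=60, seed=2)
        cos = a_small.w_star @ a_big.w_star / (
            np.linalg.norm(a_small.w_star) * np.linalg.norm(a_big.w_star)
        )
        assert cos > 0.95

    def test_report_summaries(self, default_cohort):
        report, _ = run_trials(
            default_cohort.X, default_cohort.d, default_cohort.s1, T=4, seed=0
        )
        df = report.to_frame()
        assert list(df.columns) == [
            "trial", "fold_1", "fold_2", "fold_3", "fold_4", "fold_5", "trial_mean",
        ]
        np.testing.assert_allclose(df["trial_mean"], report.trial_means)
        assert 0.0 <= report.mean <= 1.0
        assert report.sd == pytest.approx(report.trial_means.std(ddof=1))
        assert "fold_accuracies" in report.to_json()


class TestMultiTrialSVC:
    def test_estimator_interface(self, strong_cohort):
        est = MultiTrialSVC(subset=strong_cohort.s1, T=5, random_state=0)
        assert est.get_params()["T"] == 5
        est.fit(strong_cohort.X, strong_cohort.d)
        pred = est.predict(strong_cohort.X)
        assert set(np.unique(pred)) <= {1, -1}
        # a strongly separated cohort is classified well in-sample
        assert (pred == strong_cohort.d).mean() > 0.9

    def test_t_must_be_positive(self, strong_cohort):
        with pytest.raises(ValueError, match="T must be"):
            MultiTrialSVC(T=0).fit(strong_cohort.X, strong_cohort.d)
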