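import numpy as np
import pytest

from microresp import (
    block_sweep,
    cutoff_sweep,
    discarded_taxa_control,
    permutation_null,
    rank_influence,
    ranking_consistency,
    run_trials,
)
from microresp.validation import _spawn_seeds, permute_training_labels


@pytest.fixture(scope="module")
def strong_ranking(strong_cohort):
    _, avg = run_trials(
        strong_cohort.X, strong_cohort.d, strong_cohort.s1, T=20, seed=5
    )
    return rank_influence(avg, strong_cohort.s1)


class TestSweeps:
    def test_cutoff_sweep_identity_point_matches_plain_cv(self, strong_cohort, strong_ranking):
        M = strong_ranking.M
        sweep = cutoff_sweep(
            strong_cohort.X, strong_cohort.d, strong_ranking,
            T=4, cutoffs=[M], seed=7,
        )
        rep, _ = run_trials(
            strong_cohort.X, strong_cohort.d, strong_ranking.order,
            T=4, seed=_spawn_seeds(7, 1)[0],
        )
        assert sweep.table["mean"].iloc[0] == pytest.approx(rep.mean)
        assert sweep.table["dimensionality"].iloc[0] == M

    def test_pruning_to_planted_taxa_does_not_hurt(self, strong_cohort, strong_ranking):
        k = len(strong_cohort.informative)
        sweep = cutoff_sweep(
            strong_cohort.X, strong_cohort.d, strong_ranking,
            T=10, cutoffs=[k, strong_ranking.M], seed=8,
        )
        at_k = sweep.table.set_index("cutoff")["mean"]
        assert at_k.loc[k] >= at_k.loc[strong_ranking.M] - 0.02

    def test_block_sweep_first_block_is_top_block(self, strong_cohort, strong_ranking):
        sweep = block_sweep(
            strong_cohort.X, strong_cohort.d, strong_ranking,
            block_size=8, T=4, starts=[1], seed=9,
        )
        rep, _ = run_trials(
            strong_cohort.X, strong_cohort.d, strong_ranking.order[:8],
            T=4, seed=_spawn_seeds(9, 1)[0],
        )
        assert sweep.table["mean"].iloc[0] == pytest.approx(rep.mean)

    def test_block_sweep_signal_fades_down_the_ranking(self, strong_cohort, strong_ranking):
        first = block_sweep(
            strong_cohort.X, strong_cohort.d, strong_ranking,
            block_size=8, T=10, starts=[1], seed=10,
        ).table["mean"].iloc[0]
        last_start = strong_ranking.M - 8 + 1
        last = block_sweep(
            strong_cohort.X, strong_cohort.d, strong_ranking,
            block_size=8, T=10, starts=[last_start], seed=10,
        ).table["mean"].iloc[0]
        assert first > last + 0.15  # planted block far above the tail block

    def test_oversized_block_collapses_to_single_block(self, strong_cohort, strong_ranking):
        sweep = block_sweep(
            strong_cohort.X, strong_cohort.d, strong_ranking,
            block_size=strong_ranking.M + 50, T=2, seed=11,
        )
        assert len(sweep.table) == 1
        assert sweep.table["dimensionality"].iloc[0] == strong_ranking.M


class TestDiscardedTaxaControl:
    def test_null_discarded_set_stays_near_chance(self, strong_cohort):
        informative_idx = [
            list(strong_cohort.table.taxa).index(t) for t in strong_cohort.informative
        ]
        null_taxa = np.setdiff1d(strong_cohort.s1, informative_idx)[:20]
        best, sweep, _ = discarded_taxa_control(
            strong_cohort.X, strong_cohort.d, null_taxa,
            block_size=8, T=10, seed=12,
        )
        assert best == sweep.max_mean
        assert best < 0.72  # qualitative analogue of the near-chance control

    def test_planted_taxon_in_discarded_set_is_detected(self, strong_cohort):
        informative_idx = [
            list(strong_cohort.table.taxa).index(t) for t in strong_cohort.informative
        ]
        null_taxa = np.setdiff1d(strong_cohort.s1, informative_idx)[:20]
        contaminated = np.concatenate([null_taxa[:-4], informative_idx[:4]])
        best_null, *_ = discarded_taxa_control(
            strong_cohort.X, strong_cohort.d, null_taxa,
            block_size=8, T=10, seed=13,
        )
        best_cont, *_ = discarded_taxa_control(
            strong_cohort.X, strong_cohort.d, contaminated,
            block_size=8, T=10, seed=13,
        )
        assert best_cont > best_null + 0.05

    def test_empty_discarded_set(self, strong_cohort):
        with pytest.raises(ValueError, match="empty"):
            discarded_taxa_control(strong_cohort.X, strong_cohort.d, [], T=1)


class TestPermutationNull:
    def test_identity_permuter_reproduces_plain_cv(self, strong_cohort):
        plain, _ = run_trials(
            strong_cohort.X, strong_cohort.d, strong_cohort.s1, T=3, seed=21
        )
        forced, _ = run_trials(
            strong_cohort.X, strong_cohort.d, strong_cohort.s1, T=3, seed=21,
            label_permuter=lambda rng, d: d,
        )
        np.testing.assert_array_equal(plain.fold_acc, forced.fold_acc)

    def test_permuter_preserves_label_multiset(self):
        rng = np.random.default_rng(0)
        d = np.repeat([1, -1], 16)
        out = permute_training_labels(rng, d)
        assert sorted(out) == sorted(d)

    def test_null_sits_at_chance_even_with_signal(self, strong_cohort):
        report = permutation_null(
            strong_cohort.X, strong_cohort.d, strong_cohort.s1, T=40, seed=22
        )
        se = report.sd / np.sqrt(report.T)
        assert abs(report.mean - 0.5) < max(3 * se, 0.05)


class TestRankingConsistency:
    def test_identical_models_are_point_masses(self):
        w = np.array([0.9, 0.1, 0.5])
        hist = ranking_consistency([(w, 0.0)] * 10)
        assert hist.n_phases == 10
        np.testing.assert_array_equal(hist.counts.sum(axis=1), 10)
        np.testing.assert_array_equal(np.diag(hist.counts), 10)
        np.testing.assert_array_equal(hist.deviation, 0.0)

    def test_row_sums_equal_phase_count(self, strong_cohort):
        report, _ = run_trials(
            strong_cohort.X, strong_cohort.d, strong_cohort.s1, T=4, seed=23
        )
        hist = ranking_consistency(report.models, strong_cohort.s1)
        np.testing.assert_array_equal(hist.counts.sum(axis=1), 20)

    def test_top_taxa_rank_more_consistently(self, strong_cohort):
        report, _ = run_trials(
            strong_cohort.X, strong_cohort.d, strong_cohort.s1, T=20, seed=24
        )
        hist = ranking_consistency(report.models, strong_cohort.s1)
        # positive rank correlation between final rank and rank deviation:
        # influential taxa wander less across training phases
        assert hist.diagonality() > 0.3
        frame = hist.to_frame()
        assert "mean_abs_rank_deviation" in frame.columns
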