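import numpy as np
import pandas as pd
import pytest

from microresp import (
    AveragedModel,
    absence_rates,
    filter_ambiguous,
    filter_by_absence,
    parameter_search,
    rank_influence,
    select_top,
)
from microresp.containers import AbundanceTable


def make_table(x, ambiguous_cols=()):
    names = [f"T{i}" if i not in ambiguous_cols else f"Other_{i}" for i in range(x.shape[1])]
    return AbundanceTable(
        data=pd.DataFrame(x, columns=names),
        subjects=pd.Series([f"S{i}" for i in range(x.shape[0])]),
    )


class TestFilterAmbiguous:
    def test_study_count(self, default_cohort):
        s1 = filter_ambiguous(default_cohort.table)
        assert s1.size == 198  # 221 - 23 "Other" designations
        assert not default_cohort.table.ambiguous.iloc[s1].any()

    def test_no_flagged_taxa(self):
        t = make_table(np.full((2, 3), 1 / 3))
        np.testing.assert_array_equal(filter_ambiguous(t), [0, 1, 2])

    def test_all_flagged_degenerate(self):
        t = make_table(np.full((2, 2), 0.5), ambiguous_cols={0, 1})
        assert filter_ambiguous(t).size == 0


class TestAbsenceRates:
    def test_counting_example(self):
        # 8 samples, 4 per class; taxon 0 zero in half of each class
        x = np.ones((8, 2))
        x[[0, 1, 4, 5], 0] = 0.0
        x /= x.sum(axis=1, keepdims=True)
        d = np.repeat([1, -1], 4)
        rates = absence_rates(x, d)
        assert rates.loc[0, "rate_pos"] == 0.5 and rates.loc[0, "rate_neg"] == 0.5
        assert rates.loc[1, "rate_pos"] == 0.0 and rates.loc[1, "rate_neg"] == 0.0

    def test_denominators_are_class_sizes(self, default_cohort):
        rates = absence_rates(default_cohort.X, default_cohort.d, default_cohort.s1)
        # achievable rates are multiples of 1/76 and 1/20 respectively
        np.testing.assert_allclose(
            rates["rate_pos"] * 76, np.round(rates["rate_pos"] * 76), atol=1e-9
        )
        np.testing.assert_allclose(
            rates["rate_neg"] * 20, np.round(rates["rate_neg"] * 20), atol=1e-9
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            absence_rates(np.ones((3, 2)), np.array([1, 1, 1]))


class TestFilterByAbsence:
    def rates(self, pairs):
        return pd.DataFrame(
            [{"rate_pos": p, "rate_neg": n} for p, n in pairs],
            index=pd.Index(range(len(pairs)), name="taxon_index"),
        )

    def test_differential_absence_retained(self):
        kept = filter_by_absence(self.rates([(0.9, 0.2)]), threshold=0.6)
        assert list(kept) == [0]

    def test_both_exceed_removed(self):
        kept = filter_by_absence(self.rates([(0.7, 0.65)]), threshold=0.6)
        assert kept.size == 0

    def test_exceed_is_strict(self):
        kept = filter_by_absence(self.rates([(0.6, 0.6)]), threshold=0.6)
        assert list(kept) == [0]

    def test_all_zero_taxon_always_removed(self):
        for thr in (0.0, 0.5, 1.0):
            assert filter_by_absence(self.rates([(1.0, 1.0)]), thr).size == 0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            filter_by_absence(self.rates([(0.2, 0.2)]), threshold=1.5)


class TestRankInfluence:
    def test_sorting_example(self):
        avg = AveragedModel(np.array([0.5, -0.2, 0.9]), 0.0, 1)
        ranking = rank_influence(avg)
        np.testing.assert_array_equal(ranking.order, [2, 0, 1])
        assert ranking.ranks().loc[2] == 1
        assert not ranking.tied

    def test_ties_broken_by_ascending_index(self):
        avg = AveragedModel(np.array([0.3, 0.3, 0.3]), 0.0, 1)
        ranking = rank_influence(avg, S=[7, 3, 5])
        np.testing.assert_array_equal(ranking.order, [3, 5, 7])
        assert ranking.tied

    def test_single_taxon(self):
        ranking = rank_influence(AveragedModel(np.array([0.4]), 0.0, 1))
        assert ranking.M == 1 and ranking.order[0] == 0

    def test_ordering_is_valid_bijection(self):
        rng = np.random.default_rng(11)
        g = rng.normal(size=50)
        ranking = rank_influence(AveragedModel(g, 0.0, 1))
        assert sorted(ranking.order) == list(range(50))
        sorted_gains = np.abs(g)[ranking.order]
        assert (np.diff(sorted_gains) <= 1e-15).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="does not match"):
            rank_influence(AveragedModel(np.ones(3), 0.0, 1), S=[1, 2])


class TestSelectTop:
    @pytest.fixture()
    def ranking(self):
        return rank_influence(AveragedModel(np.array([0.1, 0.9, 0.5, 0.7]), 0.0, 1))

    def test_full_cutoff_identity(self, ranking):
        assert sorted(select_top(ranking, 4)) == [0, 1, 2, 3]

    def test_top_one(self, ranking):
        np.testing.assert_array_equal(select_top(ranking, 1), [1])

    def test_out_of_range(self, ranking):
        for bad in (0, 5):
            with pytest.raises(ValueError, match="cutoff"):
                select_top(ranking, bad)


class TestParameterSearch:
    def test_floor_above_one_is_unattainable(self, strong_cohort):
        with pytest.raises(ValueError, match="unattainable"):
            parameter_search(
                strong_cohort.X, strong_cohort.d, strong_cohort.s1,
                T=1, accuracy_floor=1.01,
            )

    def test_unknown_floor_rule(self, strong_cohort):
        with pytest.raises(ValueError, match="unknown accuracy_floor"):
            parameter_search(
                strong_cohort.X, strong_cohort.d, strong_cohort.s1,
                T=1, accuracy_floor="two-sd",
            )

    def test_zero_floor_selects_minimum_dimensionality(self, strong_cohort):
        surface, params, details = parameter_search(
            strong_cohort.X, strong_cohort.d, strong_cohort.s1,
            T=2, accuracy_floor=0.0, absence_grid=[0.8],
            cutoff_grid=[1, 5, 10], seed=0,
        )
        assert params.rank_cutoff == 1
        assert set(surface.grid["rank_cutoff"]) == {1, 5, 10}

    def test_unreachable_floor_reports_best(self, strong_cohort):
        with pytest.raises(ValueError, match="best achievable"):
            parameter_search(
                strong_cohort.X, strong_cohort.d, strong_cohort.s1,
                T=2, accuracy_floor=0.9999, absence_grid=[0.8],
                cutoff_grid=[2], seed=0,
            )

    def test_stage_monotonicity_and_details(self, strong_cohort):
        surface, params, details = parameter_search(
            strong_cohort.X, strong_cohort.d, strong_cohort.s1,
            T=2, accuracy_floor="one-sd", absence_grid=[0.5, 0.9],
            cutoff_grid=[4, 8], seed=1,
        )
        for thr, det in details.items():
            s2 = det["ranking"].taxa
            assert set(s2) <= set(strong_cohort.s1.tolist())
            final = select_top(det["ranking"], 4)
            assert set(final) <= set(s2.tolist())
        assert params.absence_threshold in details
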