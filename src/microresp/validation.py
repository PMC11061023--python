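"""Verification experiments for the reduction methodology.

These mirror the checks used to argue the influence ranking is genuine:
accuracy as a function of the rank cutoff; accuracy on sliding blocks of
adjacently ranked taxa (signal should fade in lower blocks); controls built
only from discarded taxa (should hover near chance); a permutation null in
which training labels are shuffled but test labels stay true (should sit at
50%); and per-taxon histograms of the ranks received across all 5T training
phases (high-influence taxa should rank consistently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crossval import N_FOLDS, POOL_PER_CLASS, CVReport, run_trials
from .reduction import GainRanking, rank_influence, select_top
from .svm import DEFAULT_C, AveragedModel, average_models


@dataclass
class SweepResult:
    """Accuracy recorded along one sweep axis (rank cutoff or block start)."""

    axis_name: str
    table: pd.DataFrame  # columns: <axis_name>, dimensionality, mean, sd

    @property
    def max_mean(self) -> float:
        return float(self.table["mean"].max())


def _spawn_seeds(seed: int, n: int):
    return [int(s.generate_state(1)[0] >> 1) for s in np.random.SeedSequence(seed).spawn(n)]


def cutoff_sweep(
    X, d, ranking: GainRanking, T: int = 200, C: float = DEFAULT_C,
    cutoffs=None, seed: int = 0,
    pool_per_class: int = POOL_PER_CLASS, n_folds: int = N_FOLDS,
) -> SweepResult:
    """Mean CV accuracy when retaining only the top-r ranked taxa, per r."""
    cuts = np.arange(1, ranking.M + 1) if cutoffs is None else np.asarray(cutoffs)
    rows = []
    for r, s in zip(cuts, _spawn_seeds(seed, len(cuts))):
        sub = select_top(ranking, int(r))
        rep, _ = run_trials(X, d, sub, T=T, C=C, seed=s,
                            pool_per_class=pool_per_class, n_folds=n_folds)
        rows.append({"cutoff": int(r), "dimensionality": sub.size,
                     "mean": rep.mean, "sd": rep.sd})
    return SweepResult(axis_name="cutoff", table=pd.DataFrame(rows))


def block_sweep(
    X, d, ranking: GainRanking, block_size: int = 19,
    T: int = 200, C: float = DEFAULT_C, starts=None, seed: int = 0,
    pool_per_class: int = POOL_PER_CLASS, n_folds: int = N_FOLDS,
) -> SweepResult:
    """Accuracy on sliding blocks of ``block_size`` adjacently ranked taxa.

    Block R uses taxa ranked R .. R+block_size-1. When the ranking holds
    fewer taxa than one block, a single block of everything is used.
    """
    if block_size > ranking.M:
        blocks = [1]
        block_size = ranking.M
    else:
        blocks = (
            np.arange(1, ranking.M - block_size + 2) if starts is None
            else np.asarray(starts)
        )
    rows = []
    for R, s in zip(blocks, _spawn_seeds(seed, len(blocks))):
        sub = ranking.order[R - 1: R - 1 + block_size]
        rep, _ = run_trials(X, d, sub, T=T, C=C, seed=s,
                            pool_per_class=pool_per_class, n_folds=n_folds)
        rows.append({"block": int(R), "dimensionality": sub.size,
                     "mean": rep.mean, "sd": rep.sd})
    return SweepResult(axis_name="block", table=pd.DataFrame(rows))


def discarded_taxa_control(
    X, d, discarded, block_size: int = 19,
    T: int = 200, C: float = DEFAULT_C, seed: int = 0,
    pool_per_class: int = POOL_PER_CLASS, n_folds: int = N_FOLDS,
):
    """Best block accuracy achievable from discarded taxa alone.

    Ranks the discarded taxa by influence (their own multi-trial averaged
    classifier), sweeps blocks of ``block_size`` across that ranking, and
    returns ``(max_accuracy, sweep, ranking)``. Discarded taxa carrying no
    signal should stay near chance; a planted taxon hidden in the set will
    elevate the maximum (a positive control of the control).
    """
    discarded = np.asarray(discarded)
    if discarded.size == 0:
        raise ValueError("discarded taxon set is empty")
    s_rank, s_sweep = _spawn_seeds(seed, 2)
    _, avg = run_trials(X, d, discarded, T=T, C=C, seed=s_rank,
                        pool_per_class=pool_per_class, n_folds=n_folds)
    ranking = rank_influence(avg, discarded)
    sweep = block_sweep(X, d, ranking, block_size=block_size, T=T, C=C,
                        seed=s_sweep, pool_per_class=pool_per_class,
                        n_folds=n_folds)
    return sweep.max_mean, sweep, ranking


def permute_training_labels(rng, d_train: np.ndarray) -> np.ndarray:
    """Uniformly permute the training labels (the permutation-null relabeler)."""
    return d_train[rng.permutation(d_train.size)]


def permutation_null(
    X, d, S, T: int = 200, C: float = DEFAULT_C, seed: int = 0,
    pool_per_class: int = POOL_PER_CLASS, n_folds: int = N_FOLDS,
) -> CVReport:
    """Multi-trial CV with training labels permuted; test labels stay true.

    The resulting "false classifiers" should achieve chance-level accuracy
    on the balanced test folds, confirming that the real pipeline exploits
    genuine class signal.
    """
    report, _ = run_trials(
        X, d, S, T=T, C=C, seed=seed,
        pool_per_class=pool_per_class, n_folds=n_folds,
        label_permuter=permute_training_labels,
    )
    return report


@dataclass
class RankHistogram:
    """Per-taxon histogram of ranks received across all training phases.

    ``counts[i, r-1]`` is how often the taxon finally ranked i+1 received
    rank r in an individual training phase; each row sums to the number of
    phases (5T). ``deviation`` is each taxon's mean absolute difference
    between per-phase rank and final rank (small for stable taxa).
    """

    taxa: np.ndarray  # ordered by final rank
    counts: np.ndarray  # (M, M)
    deviation: np.ndarray  # (M,)
    n_phases: int

    def diagonality(self) -> float:
        """Spearman correlation between final rank and rank deviation.

        Positive values mean top-ranked taxa were ranked more consistently
        across trials than bottom-ranked ones (the diagonal-concentration
        pattern)."""
        rho = sps.spearmanr(np.arange(1, self.taxa.size + 1), self.deviation)
        return float(rho.statistic)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.taxa, name="taxon_index"),
            columns=[f"rank_{r}" for r in range(1, self.counts.shape[1] + 1)],
        )
        df.insert(0, "final_rank", np.arange(1, self.taxa.size + 1))
        df["mean_abs_rank_deviation"] = self.deviation
        return df


def ranking_consistency(models, S=None) -> RankHistogram:
    """Histogram each taxon's per-phase influence rank against its final rank.

    ``models`` is the list of (w, b) pairs from every training phase (as
    stored on a :class:`CVReport`); the final ranking comes from their
    average, and each phase contributes the rank it individually assigns.
    """
    avg = average_models(models)
    final = rank_influence(avg, S)
    M = final.M
    pos = pd.Series(np.arange(M), index=final.order)  # taxon -> row in histogram
    counts = np.zeros((M, M), dtype=int)
    dev = np.zeros(M)
    for w, _b in models:
        phase = rank_influence(AveragedModel(np.asarray(w), 0.0, 1), final.taxa)
        rows = pos.loc[phase.order].to_numpy()
        ranks = np.arange(1, M + 1)
        counts[rows, ranks - 1] += 1
        dev[rows] += np.abs(ranks - (rows + 1))
    n_phases = len(models)
    return RankHistogram(
        taxa=final.order, counts=counts, deviation=dev / n_phases, n_phases=n_phases
    )
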