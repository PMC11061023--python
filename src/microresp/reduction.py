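"""Three-stage taxon elimination and the joint threshold search.

Stage 1 (ambiguity) removes taxa with the "Other" designation. Stage 2
(absence rate) removes taxa that are absent — abundance exactly zero — at a
high rate in *both* classes: a taxon is disqualified when its per-class
absence rates both strictly exceed the threshold, and taxa absent everywhere
are always removed. A taxon absent often in one class but not the other is
retained: differential absence is itself informative. Absence rates are
computed once on the full analyzed dataset, as a fixed pre-learning step.

Stage 3 (decision influence) trains the multi-trial averaged classifier on
the surviving taxa, ranks them by gain g_m = |w*_m| (descending, ties broken
by ascending taxon index), and keeps the top-ranked taxa. The two thresholds
— maximum tolerated absence rate and lowest accepted influence rank — are
chosen jointly by rerunning the full multi-trial cross-validation for each
candidate pair and picking the pair of smallest final dimensionality whose
mean accuracy still meets a floor (0.96 in the source analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceTable
from .crossval import N_FOLDS, POOL_PER_CLASS, run_trials
from .svm import DEFAULT_C, AveragedModel


def filter_ambiguous(table: AbundanceTable) -> np.ndarray:
    """Column indices of taxa without the ambiguous ("Other") designation."""
    keep = ~table.ambiguous.to_numpy(dtype=bool)
    return np.flatnonzero(keep)


def absence_rates(X, d, S=None) -> pd.DataFrame:
    """Per-taxon fraction of exactly-zero samples within each class.

    Returns a frame indexed like ``S`` (or all columns) with columns
    ``rate_pos`` (responders, d=1) and ``rate_neg`` (non-responders, d=-1);
    denominators are the class sample counts over the full dataset.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=int)
    cols = np.arange(X.shape[1]) if S is None else np.asarray(S)
    if not ((d == 1).any() and (d == -1).any()):
        raise ValueError("both classes must be present to compute absence rates")
    zero = X[:, cols] == 0
    return pd.DataFrame(
        {
            "rate_pos": zero[d == 1].mean(axis=0),
            "rate_neg": zero[d == -1].mean(axis=0),
        },
        index=pd.Index(cols, name="taxon_index"),
    )


def filter_by_absence(rates: pd.DataFrame, threshold: float) -> np.ndarray:
    """Taxa surviving the absence-rate filter.

    A taxon is removed iff BOTH class rates strictly exceed ``threshold``;
    taxa absent in every sample (both rates 1) are removed regardless.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("absence threshold must lie in [0, 1]")
    rp = rates["rate_pos"].to_numpy()
    rn = rates["rate_neg"].to_numpy()
    removed = ((rp > threshold) & (rn > threshold)) | ((rp == 1.0) & (rn == 1.0))
    return rates.index.to_numpy()[~removed]


@dataclass
class GainRanking:
    """Influence ranking of taxa by gain g_m = |w*_m|.

    ``order`` maps rank r (1-based position r-1) to a taxon id, sorted by
    descending gain with ties broken by ascending taxon index. ``gains`` is
    aligned with ``taxa`` (the unsorted id list).
    """

    taxa: np.ndarray
    gains: np.ndarray
    order: np.ndarray
    tied: bool

    @property
    def M(self) -> int:
        return self.taxa.size

    def ranks(self) -> pd.Series:
        """Taxon id -> rank (1 = most influential)."""
        return pd.Series(np.arange(1, self.M + 1), index=self.order)

    def to_frame(self) -> pd.DataFrame:
        g = pd.Series(self.gains, index=self.taxa)
        return pd.DataFrame(
            {"rank": np.arange(1, self.M + 1), "taxon_index": self.order,
             "gain": g.loc[self.order].to_numpy()}
        ).set_index("rank")


def rank_influence(avg: AveragedModel, S=None) -> GainRanking:
    """Rank taxa by the averaged classifier's gains (descending |w*|)."""
    g = avg.gains
    taxa = np.arange(g.size) if S is None else np.asarray(S)
    if taxa.size != g.size:
        raise ValueError("taxon id list does not match model dimensionality")
    # lexsort: primary key descending gain, secondary ascending taxon id
    idx = np.lexsort((taxa, -g))
    tied = bool(np.unique(g).size < g.size)
    return GainRanking(taxa=taxa, gains=g, order=taxa[idx], tied=tied)


def select_top(ranking: GainRanking, cutoff: int) -> np.ndarray:
    """Taxa with influence rank <= cutoff (the retained subset)."""
    if not 1 <= cutoff <= ranking.M:
        raise ValueError(f"cutoff must lie in [1, {ranking.M}], got {cutoff}")
    return ranking.order[:cutoff]


@dataclass
class ReductionParams:
    """The selected threshold pair: maximum tolerated absence rate and
    lowest accepted influence rank."""

    absence_threshold: float
    rank_cutoff: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.absence_threshold <= 1.0:
            raise ValueError("absence threshold must lie in [0, 1]")
        if self.rank_cutoff < 1:
            raise ValueError("rank cutoff must be at least 1")


@dataclass
class AccuracySurface:
    """Grid of (absence threshold, rank cutoff) -> second-stage accuracy."""

    grid: pd.DataFrame  # columns: absence_threshold, rank_cutoff, dimensionality, mean, sd

    def resolve_floor(self, floor) -> float:
        """Resolve a floor specification to a number.

        A float is used as-is. The string ``"one-sd"`` applies a
        one-standard-deviation plateau rule: the floor is the surface's best
        mean accuracy minus the trial-to-trial sd at that best cell, so the
        search keeps any cell statistically indistinguishable from the peak.
        """
        if floor == "one-sd":
            best = self.grid.loc[self.grid["mean"].idxmax()]
            return float(best["mean"] - best["sd"])
        return float(floor)

    def best_meeting_floor(self, floor) -> pd.Series:
        floor = self.resolve_floor(floor)
        ok = self.grid[self.grid["mean"] >= floor]
        if ok.empty:
            best = self.grid.loc[self.grid["mean"].idxmax()]
            raise ValueError(
                f"no parameter pair reaches the accuracy floor {floor:.4f}; "
                f"best achievable is {best['mean']:.4f} at absence threshold "
                f"{best['absence_threshold']:.4f}, cutoff {int(best['rank_cutoff'])}"
            )
        ok = ok.sort_values(
            ["dimensionality", "mean"], ascending=[True, False], kind="mergesort"
        )
        return ok.iloc[0]


def achievable_rate_grid(rates: pd.DataFrame) -> np.ndarray:
    """Sorted union of the achievable per-class absence rates (< 1)."""
    vals = np.union1d(rates["rate_pos"].to_numpy(), rates["rate_neg"].to_numpy())
    return vals[vals < 1.0]


def parameter_search(
    X,
    d,
    S,
    T: int = 200,
    C: float = DEFAULT_C,
    accuracy_floor: float = 0.96,
    absence_grid=None,
    cutoff_grid=None,
    seed: int = 0,
    pool_per_class: int = POOL_PER_CLASS,
    n_folds: int = N_FOLDS,
):
    """Joint search over absence-rate threshold and influence-rank cutoff.

    For each candidate absence threshold the absence filter is applied to
    ``S`` (which should already exclude ambiguous taxa), a first multi-trial
    CV yields the averaged classifier and its influence ranking, and each
    candidate cutoff is evaluated with a fresh second-stage multi-trial CV on
    the retained taxa. The returned pair has the smallest final
    dimensionality among cells meeting ``accuracy_floor``; ties go to the
    higher accuracy. ``accuracy_floor`` may be a number in [0, 1] or
    ``"one-sd"`` (floor one trial-sd below the surface's peak accuracy; see
    :meth:`AccuracySurface.resolve_floor`).

    ``absence_grid`` defaults to every achievable per-class absence rate and
    ``cutoff_grid`` to every rank — exhaustive and expensive; pass coarser
    grids for exploratory runs.

    Returns ``(surface, params, details)`` where ``details`` maps each
    absence threshold to its stage-1 report and ranking.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=int)
    S = np.asarray(S)
    if not isinstance(accuracy_floor, str) and not 0.0 <= accuracy_floor <= 1.0:
        raise ValueError(
            f"accuracy floor must lie in [0, 1]; {accuracy_floor} is unattainable"
        )
    if isinstance(accuracy_floor, str) and accuracy_floor != "one-sd":
        raise ValueError(f"unknown accuracy_floor rule {accuracy_floor!r}")
    rates_all = absence_rates(X, d, S)
    if absence_grid is None:
        absence_grid = achievable_rate_grid(rates_all)
    absence_grid = np.asarray(sorted(set(float(a) for a in absence_grid)))

    ss = np.random.SeedSequence(seed)
    rows = []
    details = {}
    for a, child in zip(absence_grid, ss.spawn(len(absence_grid))):
        s2 = filter_by_absence(rates_all, a)
        if s2.size == 0:
            continue
        seed1, seed2 = (int(c.generate_state(1)[0] >> 1) for c in child.spawn(2))
        report1, avg1 = run_trials(
            X, d, s2, T=T, C=C, seed=seed1,
            pool_per_class=pool_per_class, n_folds=n_folds,
        )
        ranking = rank_influence(avg1, s2)
        details[float(a)] = {"stage1_report": report1, "ranking": ranking}
        cuts = (
            np.arange(1, s2.size + 1)
            if cutoff_grid is None
            else np.asarray([c for c in cutoff_grid if 1 <= c <= s2.size])
        )
        seeds2 = np.random.SeedSequence(seed2).spawn(len(cuts))
        for r, c2 in zip(cuts, seeds2):
            s3 = select_top(ranking, int(r))
            report2, _ = run_trials(
                X, d, s3, T=T, C=C,
                seed=int(c2.generate_state(1)[0] >> 1),
                pool_per_class=pool_per_class, n_folds=n_folds,
            )
            rows.append(
                {
                    "absence_threshold": float(a),
                    "rank_cutoff": int(r),
                    "dimensionality": int(s3.size),
                    "mean": report2.mean,
                    "sd": report2.sd,
                }
            )
    if not rows:
        raise ValueError("parameter grid produced no evaluable cells")
    surface = AccuracySurface(grid=pd.DataFrame(rows))
    chosen = surface.best_meeting_floor(accuracy_floor)
    params = ReductionParams(
        absence_threshold=float(chosen["absence_threshold"]),
        rank_cutoff=int(chosen["rank_cutoff"]),
    )
    return surface, params, details
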