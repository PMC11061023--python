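"""Class-balanced multi-trial five-fold cross-validation.

The study's sample classes are heavily imbalanced (76 responder vs 20
non-responder samples), so each trial first draws a balanced working dataset:
20 samples per class without replacement (when a class holds exactly 20, all
of them are used every draw). Each class pool is split into five partitions
of four and the partitions are paired across classes, giving five balanced
folds of eight. Each fold takes a turn as the test set while the remaining
K = 32 samples train a linear SVM; whenever the training set changes, the
standardization statistics are refit on it and every sample is re-scored.

Trials are repeated T times (T = 200 in the source analysis) with fresh
draws; accuracy is aggregated over the 5T folds and the 5T classifiers are
averaged elementwise into the consensus hyperplane (w*, b*).

Samples, not subjects, are the resampling unit, mirroring the source
procedure; an optional subject-grouped mode keeps all of a subject's samples
in the same fold for those who want to rule out within-subject leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .preprocessing import (
    CompositionalPreprocessor,
    fit_stats,
    sqrt_transform,
    standardize,
    subset_and_renormalize,
)
from .svm import DEFAULT_C, AveragedModel, LinearMarginSVC, average_models

POOL_PER_CLASS = 20
N_FOLDS = 5


@dataclass
class BalancedDraw:
    """One balanced working dataset: per-class pools and paired folds.

    ``folds`` holds global sample indices; the folds partition the pooled
    samples, each fold balanced across classes.
    """

    pos_pool: np.ndarray
    neg_pool: np.ndarray
    folds: list  # list of ndarray of global sample indices

    @property
    def pool(self) -> np.ndarray:
        return np.concatenate([self.pos_pool, self.neg_pool])

    def validate(self) -> None:
        allidx = np.concatenate(self.folds)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("folds overlap")
        if set(allidx.tolist()) != set(self.pool.tolist()):
            raise ValueError("folds do not partition the balanced pool")


def _partition(pool: np.ndarray, n_folds: int, rng) -> list:
    perm = rng.permutation(pool)
    return np.array_split(perm, n_folds)


def draw_balanced(
    d,
    rng,
    pool_per_class: int = POOL_PER_CLASS,
    n_folds: int = N_FOLDS,
    subject_of=None,
) -> BalancedDraw:
    """Draw one balanced working dataset and its five paired folds.

    Parameters
    ----------
    d : array-like of {1, -1}
        Sample labels (positional; indices into the feature matrix).
    rng : numpy.random.Generator
    pool_per_class : int
        Samples drawn without replacement from each class (must be divisible
        by ``n_folds``).
    subject_of : array-like, optional
        Per-sample subject ids; when given, whole subjects are drawn and each
        fold holds complete subjects only (grouped mode).
    """
    d = np.asarray(d, dtype=int)
    if pool_per_class % n_folds:
        raise ValueError(
            f"pool_per_class={pool_per_class} must be divisible by n_folds={n_folds}"
        )
    pools = {}
    for cls in (1, -1):
        idx = np.flatnonzero(d == cls)
        if idx.size < pool_per_class:
            raise ValueError(
                f"class {cls} has only {idx.size} samples; "
                f"{pool_per_class} required per class"
            )
        if subject_of is None:
            pools[cls] = rng.choice(idx, size=pool_per_class, replace=False)
        else:
            pools[cls] = _draw_subject_pool(idx, np.asarray(subject_of), pool_per_class, rng)

    if subject_of is None:
        parts_pos = _partition(pools[1], n_folds, rng)
        parts_neg = _partition(pools[-1], n_folds, rng)
    else:
        subj = np.asarray(subject_of)
        parts_pos = _partition_by_subject(pools[1], subj, n_folds, rng)
        parts_neg = _partition_by_subject(pools[-1], subj, n_folds, rng)
    folds = [np.concatenate([p, q]) for p, q in zip(parts_pos, parts_neg)]
    draw = BalancedDraw(pos_pool=pools[1], neg_pool=pools[-1], folds=folds)
    draw.validate()
    return draw


def _draw_subject_pool(idx, subj, pool_per_class, rng):
    groups = pd.Series(np.arange(len(subj))[idx], index=subj[idx]).groupby(level=0)
    sizes = groups.size()
    u = int(sizes.iloc[0])
    if not (sizes == u).all():
        raise ValueError("grouped mode requires equal samples per subject within a class")
    if pool_per_class % u:
        raise ValueError(
            f"pool_per_class={pool_per_class} not divisible by samples per subject ({u})"
        )
    need = pool_per_class // u
    subjects = sizes.index.to_numpy()
    if subjects.size < need:
        raise ValueError(
            f"class has {subjects.size} subjects; {need} required for grouped draw"
        )
    chosen = rng.choice(subjects, size=need, replace=False)
    return np.concatenate([groups.get_group(s).to_numpy() for s in chosen])


def _partition_by_subject(pool, subj, n_folds, rng):
    subjects = pd.unique(subj[pool])
    if len(subjects) % n_folds:
        raise ValueError(
            f"{len(subjects)} pooled subjects not divisible into {n_folds} folds"
        )
    perm = rng.permutation(subjects)
    chunks = np.array_split(perm, n_folds)
    bysub = pd.Series(pool, index=subj[pool])
    return [np.concatenate([np.atleast_1d(bysub.loc[s]) for s in c]) for c in chunks]


def run_cv_trial(
    X,
    d,
    S,
    draw: BalancedDraw,
    C: float = DEFAULT_C,
    label_permuter=None,
    rng=None,
):
    """Run one five-fold trial on a balanced draw.

    For each fold, standardization statistics are fit on that fold's training
    samples only, a linear SVM is trained there, and accuracy is the fraction
    of the held-out fold classified correctly.

    ``label_permuter``, if given, is called as ``label_permuter(rng, d_train)``
    before each training phase and must return relabeled training labels; test
    labels always stay true (used by the permutation-null validation).

    Returns ``(fold_accuracies, models)`` with one fitted
    :class:`LinearMarginSVC` per fold.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=int)
    # all-absent rows stay as zero compositions so fold geometry is intact
    ytil = sqrt_transform(subset_and_renormalize(X, S, zero_policy="zero"))

    accs = np.empty(len(draw.folds))
    models = []
    pool = draw.pool
    for k, test_idx in enumerate(draw.folds):
        train_idx = np.setdiff1d(pool, test_idx)
        stats = fit_stats(ytil, train_idx)
        z_train = standardize(ytil[train_idx], stats)
        z_test = standardize(ytil[test_idx], stats)
        d_train = d[train_idx]
        if label_permuter is not None:
            d_train = label_permuter(rng, d_train)
        model = LinearMarginSVC(C=C).fit(z_train, d_train)
        pred = model.predict(z_test)
        accs[k] = float(np.mean(pred == d[test_idx]))
        models.append(model)
    return accs, models


@dataclass
class CVReport:
    """Aggregated multi-trial cross-validation accuracies.

    ``fold_acc`` is T x n_folds; ``mean`` is the overall mean accuracy; ``sd``
    is the standard deviation of the T per-trial means (the "+/-" reported
    alongside accuracies); ``sd_folds`` is the sd over all 5T fold
    accuracies.
    """

    fold_acc: np.ndarray
    models: list = field(repr=False)  # list of (w, b) per training phase

    @property
    def T(self) -> int:
        return self.fold_acc.shape[0]

    @property
    def trial_means(self) -> np.ndarray:
        return self.fold_acc.mean(axis=1)

    @property
    def mean(self) -> float:
        return float(self.fold_acc.mean())

    @property
    def sd(self) -> float:
        return float(self.trial_means.std(ddof=1)) if self.T > 1 else 0.0

    @property
    def sd_folds(self) -> float:
        return float(self.fold_acc.std(ddof=1)) if self.fold_acc.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fold_acc,
            columns=[f"fold_{k + 1}" for k in range(self.fold_acc.shape[1])],
        )
        df.insert(0, "trial", np.arange(1, self.T + 1))
        df["trial_mean"] = self.trial_means
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "T": self.T,
                "mean": self.mean,
                "sd_trial_means": self.sd,
                "sd_folds": self.sd_folds,
                "fold_accuracies": self.fold_acc.tolist(),
            },
            indent=1,
        )


class MultiTrialSVC(ClassifierMixin, BaseEstimator):
    """Meta-estimator: balanced multi-trial five-fold CV with model averaging.

    Fitting draws ``T`` balanced working datasets, runs five-fold
    cross-validation on each (refitting standardization per fold), and
    averages the 5T linear classifiers into a consensus hyperplane. The
    fitted estimator predicts with (w*, b*) after standardizing new samples
    with statistics learned on all samples seen at fit time.

    Parameters
    ----------
    subset : array-like of column indices or None
        Taxon subset the classifier works on.
    T : int
        Number of reshuffled trials (source analysis: 200).
    C : float
        SVM slack cost (source analysis: 10).
    pool_per_class, n_folds : int
        Balanced-draw geometry (20 per class, five folds of eight).
    grouped : bool
        Keep each subject's samples within one fold (requires ``subject_of``
        passed to :meth:`fit`).
    random_state : int
        Master seed; per-trial streams are derived deterministically.
    """

    def __init__(
        self,
        subset=None,
        T: int = 200,
        C: float = DEFAULT_C,
        pool_per_class: int = POOL_PER_CLASS,
        n_folds: int = N_FOLDS,
        grouped: bool = False,
        random_state: int = 0,
    ):
        self.subset = subset
        self.T = T
        self.C = C
        self.pool_per_class = pool_per_class
        self.n_folds = n_folds
        self.grouped = grouped
        self.random_state = random_state

    def fit(self, X, d, subject_of=None, label_permuter=None):
        X = np.asarray(X, dtype=float)
        d = np.asarray(d, dtype=int)
        if self.T < 1:
            raise ValueError("T must be at least 1")
        if self.grouped and subject_of is None:
            raise ValueError("grouped mode requires subject_of")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.T)
        fold_acc = np.empty((self.T, self.n_folds))
        models: list[tuple[np.ndarray, float]] = []
        for t, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            draw = draw_balanced(
                d,
                rng,
                pool_per_class=self.pool_per_class,
                n_folds=self.n_folds,
                subject_of=subject_of if self.grouped else None,
            )
            accs, trial_models = run_cv_trial(
                X, d, self.subset, draw, C=self.C,
                label_permuter=label_permuter, rng=rng,
            )
            fold_acc[t] = accs
            models.extend((m.w_, m.b_) for m in trial_models)
        self.report_ = CVReport(fold_acc=fold_acc, models=models)
        avg = average_models(models)
        self.w_star_ = avg.w_star
        self.b_star_ = avg.b_star
        self.averaged_ = avg
        self.preprocessor_ = CompositionalPreprocessor(
            subset=self.subset, zero_policy="zero"
        ).fit(X)
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "averaged_")
        return self.averaged_.decision_function(self.preprocessor_.transform(X))

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


def run_trials(
    X,
    d,
    S=None,
    T: int = 200,
    C: float = DEFAULT_C,
    seed: int = 0,
    pool_per_class: int = POOL_PER_CLASS,
    n_folds: int = N_FOLDS,
    subject_of=None,
    grouped: bool = False,
    label_permuter=None,
) -> tuple[CVReport, AveragedModel]:
    """Run T balanced five-fold trials; thin wrapper over MultiTrialSVC."""
    est = MultiTrialSVC(
        subset=S, T=T, C=C, pool_per_class=pool_per_class,
        n_folds=n_folds, grouped=grouped, random_state=seed,
    ).fit(X, d, subject_of=subject_of, label_permuter=label_permuter)
    return est.report_, est.averaged_
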