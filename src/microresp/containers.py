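"""In-memory containers for abundance, calcium, and label data.

The central object is :class:`AbundanceTable`, a compositional samples x taxa
matrix (rows sum to 1) with subject assignments and a per-taxon ambiguity flag
for taxa that could not be definitively classified ("Other" designations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Tolerance on row sums of a compositional matrix.
ROW_SUM_TOL = 1e-9

#: String marking a taxon name as ambiguous ("Other" designation).
AMBIGUOUS_MARKER = "Other"


@dataclass
class AbundanceTable:
    """Relative-abundance table: samples as rows, taxa as columns.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative matrix with one row per sample and one column per taxon.
        Each row sums to 1 (within ``ROW_SUM_TOL``).
    subjects : pandas.Series
        Maps each sample id (the index of ``data``) to a subject id.
    ambiguous : pandas.Series
        Boolean flag per taxon name marking "Other" designations. If omitted
        it is inferred from taxon names containing ``AMBIGUOUS_MARKER``.
    """

    data: pd.DataFrame
    subjects: pd.Series
    ambiguous: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ambiguous is None:
            self.ambiguous = pd.Series(
                [AMBIGUOUS_MARKER in str(t) for t in self.data.columns],
                index=self.data.columns,
                dtype=bool,
            )
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        x = self.data.to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValueError("abundance entries must be non-negative")
        if not np.all(np.isfinite(x)):
            raise ValueError("abundance entries must be finite")
        sums = x.sum(axis=1)
        bad = np.abs(sums - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            offender = self.data.index[int(np.argmax(bad))]
            raise ValueError(
                f"abundance rows must sum to 1 within {ROW_SUM_TOL}; "
                f"sample {offender!r} sums to {sums[np.argmax(bad)]:.12f}"
            )
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        if not self.data.index.equals(self.subjects.index):
            missing = self.data.index.difference(self.subjects.index)
            raise ValueError(f"samples without subject assignment: {list(missing)[:5]}")
        if not self.ambiguous.index.equals(pd.Index(self.data.columns)):
            raise ValueError("ambiguity flags must be indexed by taxon name")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def taxa(self) -> pd.Index:
        return pd.Index(self.data.columns)

    def values(self) -> np.ndarray:
        """The abundance matrix as a float ndarray (samples x taxa)."""
        return self.data.to_numpy(dtype=float)


@dataclass
class LabelVector:
    """Sample-level responder labels expanded from subject-level calls.

    All samples belonging to one subject carry the subject's label, with
    1 = responder and -1 = non-responder.
    """

    per_sample: pd.Series  # sample id -> {1, -1}
    per_subject: pd.Series  # subject id -> {1, -1}
    subject_of: pd.Series  # sample id -> subject id

    def __post_init__(self) -> None:
        vals = set(self.per_sample.unique()) | set(self.per_subject.unique())
        if not vals <= {1, -1}:
            raise ValueError(f"labels must be in {{1, -1}}, got {sorted(vals)}")
        for s in self.per_sample.index:
            subj = self.subject_of.loc[s]
            if self.per_sample.loc[s] != self.per_subject.loc[subj]:
                raise ValueError(f"sample {s!r} label disagrees with subject {subj!r}")

    @property
    def counts(self) -> dict[int, int]:
        """Sample counts per class, keyed by label."""
        vc = self.per_sample.value_counts()
        return {1: int(vc.get(1, 0)), -1: int(vc.get(-1, 0))}

    def to_array(self, sample_order=None) -> np.ndarray:
        if sample_order is None:
            return self.per_sample.to_numpy(dtype=int)
        return self.per_sample.loc[sample_order].to_numpy(dtype=int)


def make_calcium_table(records) -> pd.DataFrame:
    """Build a tidy calcium table (columns subject, dose, absorption).

    Doses are in g/day of soluble corn fiber (0, 10 or 20); absorption is a
    fractional calcium absorption in [0, 1]. At most one record is allowed
    per (subject, dose) pair.
    """
    df = pd.DataFrame(records, columns=["subject", "dose", "absorption"])
    df["dose"] = df["dose"].astype(int)
    df["absorption"] = df["absorption"].astype(float)
    dup = df.duplicated(subset=["subject", "dose"])
    if dup.any():
        pair = df.loc[dup, ["subject", "dose"]].iloc[0]
        raise ValueError(
            f"duplicate calcium record for subject {pair['subject']!r} dose {pair['dose']}"
        )
    ok = df["absorption"].isna() | ((df["absorption"] >= 0) & (df["absorption"] <= 1))
    if not ok.all():
        raise ValueError("fractional absorption must lie in [0, 1]")
    return df
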