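"""Responder labeling from fractional calcium absorption.

A subject is a responder (label 1) if fractional calcium absorption at any
available non-control fiber dose exceeds the 0 g/day control by at least a
threshold (default 0.03, read as an absolute increase in fractional
absorption; a relative mode — ratio minus one — is also provided). Subjects
with a single available non-control dose are labeled on that dose alone.
Subject labels are then expanded to every sample the subject contributed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import LabelVector

CONTROL_DOSE = 0


class UnlabelableError(ValueError):
    """A subject's calcium records do not support a responder call."""


def label_subject(records, threshold: float = 0.03, mode: str = "absolute") -> int:
    """Classify one subject as responder (1) or non-responder (-1).

    Parameters
    ----------
    records : mapping or DataFrame
        Either ``{dose: absorption}`` or a tidy frame with columns ``dose``
        and ``absorption`` for a single subject. Missing values (NaN) are
        treated as absent records.
    threshold : float
        Minimum increase over control counted as a response (inclusive).
    mode : {"absolute", "relative"}
        Absolute: ``absorption - control >= threshold``.
        Relative: ``absorption / control - 1 >= threshold``.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"mode must be 'absolute' or 'relative', got {mode!r}")
    if isinstance(records, pd.DataFrame):
        rec = {int(r["dose"]): float(r["absorption"]) for _, r in records.iterrows()}
    else:
        rec = {int(k): float(v) for k, v in dict(records).items()}
    rec = {k: v for k, v in rec.items() if not math.isnan(v)}

    if CONTROL_DOSE not in rec:
        raise UnlabelableError("no control (0 g/day) absorption record")
    control = rec[CONTROL_DOSE]
    doses = sorted(k for k in rec if k != CONTROL_DOSE)
    if not doses:
        raise UnlabelableError("no non-control absorption record")

    for dose in doses:
        if mode == "absolute":
            increase = rec[dose] - control
        else:
            if control <= 0:
                raise UnlabelableError("relative mode requires positive control absorption")
            increase = rec[dose] / control - 1.0
        if increase >= threshold:
            return 1
    return -1


def label_subjects(
    calcium: pd.DataFrame, threshold: float = 0.03, mode: str = "absolute"
) -> pd.Series:
    """Apply :func:`label_subject` to every subject in a tidy calcium table."""
    labels = {}
    for subj, grp in calcium.groupby("subject", sort=False):
        labels[subj] = label_subject(grp, threshold=threshold, mode=mode)
    return pd.Series(labels, dtype=int)


def expand_labels(subject_labels: pd.Series, subject_of: pd.Series) -> LabelVector:
    """Expand subject-level labels to sample-level labels.

    ``subject_of`` maps sample id -> subject id. Every sample must map to a
    labeled subject; orphans raise with the sample named.
    """
    missing = [
        s for s in subject_of.index if subject_of.loc[s] not in subject_labels.index
    ]
    if missing:
        raise ValueError(
            f"sample {missing[0]!r} maps to subject {subject_of.loc[missing[0]]!r} "
            "which has no label"
        )
    per_sample = pd.Series(
        subject_labels.loc[subject_of].to_numpy(dtype=int), index=subject_of.index
    )
    return LabelVector(
        per_sample=per_sample,
        per_subject=subject_labels.astype(int),
        subject_of=subject_of,
    )
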