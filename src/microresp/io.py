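"""Tab-separated text I/O and run configuration.

Formats:
  abundance table — TSV, first column ``sample``, optional second column
    ``subject``, remaining columns one per taxon; rows must sum to 1 within
    1e-6 (they are renormalized exactly on read); taxon names containing
    "Other" are flagged ambiguous.
  calcium table — TSV with columns subject, dose, absorption.
  labels — TSV with columns sample, subject, label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AbundanceTable, LabelVector, make_calcium_table

READ_SUM_TOL = 1e-6


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.insert(0, "subject", table.subjects)
    df.to_csv(path, sep="\t", index_label="sample")


def read_abundance_table(path) -> AbundanceTable:
    """Read and validate a TSV abundance table.

    Rejects negative entries, duplicate sample ids, and rows whose sum is off
    1 by more than 1e-6; surviving rows are renormalized to sum exactly 1.
    """
    df = pd.read_csv(path, sep="\t", index_col="sample", float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if "subject" in df.columns:
        subjects = df.pop("subject").astype(str)
    else:
        subjects = pd.Series(df.index.astype(str), index=df.index)
    x = df.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance entry")
    sums = x.sum(axis=1)
    bad = np.abs(sums - 1.0) > READ_SUM_TOL
    if bad.any():
        offender = df.index[int(np.argmax(bad))]
        raise ValueError(
            f"row {offender!r} sums to {sums[np.argmax(bad)]:.6f}, "
            f"outside 1 +/- {READ_SUM_TOL}"
        )
    # renormalize only rows that deviate, so clean files round-trip exactly
    off = np.abs(sums - 1.0) > 1e-12
    x[off] = x[off] / sums[off, None]
    return AbundanceTable(
        data=pd.DataFrame(x, index=df.index, columns=df.columns), subjects=subjects
    )


def write_calcium_table(calcium: pd.DataFrame, path) -> None:
    calcium.to_csv(path, sep="\t", index=False)


def read_calcium_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"subject", "dose", "absorption"}
    if not need <= set(df.columns):
        raise ValueError(f"calcium table must have columns {sorted(need)}")
    df["subject"] = df["subject"].astype(str)
    return make_calcium_table(df[["subject", "dose", "absorption"]])


def write_labels(labels: LabelVector, path) -> None:
    pd.DataFrame(
        {
            "sample": labels.per_sample.index,
            "subject": labels.subject_of.loc[labels.per_sample.index].to_numpy(),
            "label": labels.per_sample.to_numpy(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> LabelVector:
    df = pd.read_csv(path, sep="\t")
    per_sample = pd.Series(df["label"].to_numpy(dtype=int), index=df["sample"].astype(str))
    subject_of = pd.Series(df["subject"].astype(str).to_numpy(), index=df["sample"].astype(str))
    per_subject = (
        pd.DataFrame({"subject": subject_of.to_numpy(), "label": per_sample.to_numpy()})
        .drop_duplicates()
        .set_index("subject")["label"]
    )
    if per_subject.index.has_duplicates:
        raise ValueError("a subject carries conflicting labels")
    return LabelVector(per_sample=per_sample, per_subject=per_subject, subject_of=subject_of)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the source analysis' settings."""

    abundance_path: str | None = None
    calcium_path: str | None = None
    C: float = 10.0
    T: int = 200
    pool_per_class: int = 20
    n_folds: int = 5
    responder_threshold: float = 0.03
    responder_mode: str = "absolute"
    accuracy_floor: float = 0.96
    block_size: int = 19
    seed: int = 0
    out_dir: str | None = None
    # coarse grids may be supplied for exploratory runs; None = exhaustive
    absence_grid: list | None = None
    cutoff_grid: list | None = None
    run_validation: bool = True
    permutation_T: int | None = None  # defaults to T

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return {str(k): _jsonable(v) if isinstance(v, (np.generic, np.ndarray)) else v
                for k, v in o.items()}
    raise TypeError(f"not JSON serializable: {type(o)}")
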