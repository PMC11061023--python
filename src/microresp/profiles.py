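"""Class-conditional profiles of square-root abundances.

For each retained taxon the empirical distribution of its sqrt abundance is
compared between responders (D=1) and non-responders (D=-1): the raw
samples, a kernel density estimate where the sample admits one, and the
median — on the same sqrt scale the classifier sees (subset + renormalize
over the final taxon set, then square root). A separation score (one minus
the empirical density overlap) quantifies how distinct the two class
distributions are.

Marginal, per-taxon views can obscure relationships between taxa, so
profiles carry a caveat flag and no automatic inference is drawn from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .preprocessing import sqrt_transform, subset_and_renormalize

#: Caution attached to every profile: taxa must be interpreted jointly.
MARGINAL_CAVEAT = (
    "Per-taxon marginal distributions can obscure inter-taxon relationships; "
    "interpret jointly with the other retained taxa."
)


@dataclass
class ConditionalProfile:
    """Empirical sqrt-abundance distribution of one taxon in one class."""

    taxon: object
    cls: int  # 1 responder, -1 non-responder
    values: np.ndarray
    median: float
    density: object | None = field(default=None, repr=False)  # gaussian_kde or None
    caveat: str = MARGINAL_CAVEAT

    def evaluate_density(self, grid) -> np.ndarray | None:
        if self.density is None:
            return None
        return self.density(np.asarray(grid))


def _kde_or_none(values: np.ndarray):
    if np.unique(values).size < 2:
        return None  # degenerate (constant) sample: keep raw values only
    return gaussian_kde(values)  # scott's rule bandwidth


def conditional_profiles(X, d, S=None, scale: str = "final"):
    """Per-taxon, per-class sqrt-abundance profiles.

    ``scale="final"`` (default) renormalizes over the taxon subset ``S``
    before the square root — the composition the classifier actually sees;
    ``scale="original"`` takes sqrt abundances on the full-table composition.

    Returns a list of ``(responder_profile, nonresponder_profile)`` pairs,
    one per taxon in ``S``.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=int)
    cols = np.arange(X.shape[1]) if S is None else np.asarray(S)
    if scale == "final":
        # all-absent rows stay zero compositions rather than erroring out
        ytil = sqrt_transform(subset_and_renormalize(X, cols, zero_policy="zero"))
    elif scale == "original":
        ytil = sqrt_transform(X[:, cols])
    else:
        raise ValueError(f"scale must be 'final' or 'original', got {scale!r}")

    pairs = []
    for j, taxon in enumerate(cols):
        per_class = []
        for cls in (1, -1):
            vals = ytil[d == cls, j]
            if vals.size == 0:
                raise ValueError(f"class {cls} has no samples")
            per_class.append(
                ConditionalProfile(
                    taxon=taxon,
                    cls=cls,
                    values=vals,
                    median=float(np.median(vals)),
                    density=_kde_or_none(vals),
                )
            )
        pairs.append(tuple(per_class))
    return pairs


def separation_score(pair, n_bins: int = 20) -> float:
    """1 minus the empirical density overlap of the two class samples.

    Both samples are histogrammed on shared bins spanning their joint range
    and normalized to unit mass; the overlap is the summed bin-wise minimum.
    Identical samples score 0; disjoint supports score 1. Symmetric in the
    two classes.
    """
    a, b = (np.asarray(p.values, dtype=float) for p in pair)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all observations identical across both classes
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    overlap = np.minimum(pa / pa.sum(), pb / pb.sum()).sum()
    return float(1.0 - overlap)


def profile_table(pairs, taxon_names=None) -> pd.DataFrame:
    """Summary frame: per-taxon class medians and separation scores."""
    rows = []
    for pos, neg in pairs:
        name = pos.taxon if taxon_names is None else taxon_names[pos.taxon]
        rows.append(
            {
                "taxon": name,
                "median_responder": pos.median,
                "median_nonresponder": neg.median,
                "separation": separation_score((pos, neg)),
            }
        )
    return pd.DataFrame(rows)
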