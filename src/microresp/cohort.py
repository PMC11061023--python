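"""Synthetic cohort generator.

Emulates the statistical structure of a prebiotic crossover study in which
each subject contributes several baseline fecal-microbiome samples (relative
abundances over a fixed taxon list) plus fractional calcium absorption
measured at soluble-corn-fiber doses of 0, 10 and 20 g/day. The study whose
shape the defaults follow had 24 subjects x 4 samples = 96 samples over 221
taxa (23 of them ambiguous "Other" designations) with a 19/5
responder/non-responder subject split.

The generator is a stand-in with the right gross structure — compositional
rows, heavy per-taxon sparsity, a small planted set of taxa whose
class-conditional square-root abundance distributions differ — not a fitted
model of real 16S data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import AbundanceTable, make_calcium_table

#: Mean fractional calcium absorption per class per dose (g/day), as printed
#: in the source study's summary table.
DEFAULT_ABSORPTION_MEANS = {
    1: {0: 0.3503, 10: 0.4051, 20: 0.4062},
    -1: {0: 0.3840, 10: 0.3484, 20: 0.3471},
}

# Spread of per-taxon base abundances (log scale) and the within-taxon
# coefficient of variation of sqrt abundance. Fixed, not exposed: they shape
# realism (a few dominant taxa, a long sparse tail), not the study conditions.
_LOGNORMAL_SIGMA = 1.5
_SQRT_CV = 0.35


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the source study's shape: 24 subjects x 4 samples,
    221 taxa with 23 ambiguous, a 19/24 responder fraction, calcium
    absorption means per dose and class from the study's summary table.

    ``effect_size`` is the class-conditional shift of mean sqrt abundance for
    each informative taxon, expressed in units of that taxon's sqrt-abundance
    standard deviation (so it reads like a standardized effect).
    ``sparsity`` is the target fraction of zero entries per taxon.
    ``n_missing_dose`` optionally drops one non-control absorption record for
    that many subjects, emulating partially missing outcome data.

    ``subject_sd`` is the standard deviation of a per-subject latent factor
    shared by all informative taxa (loading along the class axis, in
    per-taxon sd units). It models the informative taxa as one co-varying
    guild whose overall load differs between hosts — the samples of one
    subject are correlated, and classification accuracy saturates only as
    many guild taxa are pooled.

    ``n_subject_deficits`` and ``deficit_scale`` add host-specific
    heterogeneity to the non-responder class: each non-responder subject
    deviates strongly (``deficit_scale`` x ``effect_size``, in per-taxon sd
    units) on its own random draw of ``n_subject_deficits`` informative taxa
    — different subjects lack (or overgrow) different key taxa, so reliable
    classification needs coverage of the whole informative panel, not just
    its strongest members. All class-linked structure scales with
    ``effect_size``; setting it to 0 yields a null cohort.
    """

    n_subjects: int = 24
    samples_per_subject: int = 4
    n_taxa: int = 221
    n_ambiguous: int = 23
    n_informative: int = 19
    effect_size: float = 1.0
    sparsity: float = 0.6
    subject_sd: float = 0.3
    n_subject_deficits: int = 2
    deficit_scale: float = 2.5
    responder_fraction: float = 19 / 24
    absorption_means: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_ABSORPTION_MEANS.items()
    })
    absorption_sd: float = 0.02
    n_missing_dose: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.samples_per_subject < 1 or self.n_taxa < 1:
            raise ValueError("cohort counts must be positive")
        if self.n_informative + self.n_ambiguous > self.n_taxa:
            raise ValueError(
                "invariant violated: n_informative + n_ambiguous must not exceed n_taxa "
                f"({self.n_informative} + {self.n_ambiguous} > {self.n_taxa})"
            )
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError(
                f"invariant violated: responder_fraction must lie in [0, 1], "
                f"got {self.responder_fraction}"
            )
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        if not 0 <= self.n_subject_deficits <= self.n_informative:
            raise ValueError(
                "n_subject_deficits must lie in [0, n_informative]"
            )
        if self.deficit_scale < 0:
            raise ValueError("deficit_scale must be non-negative")
        for cls, per_dose in self.absorption_means.items():
            for dose, m in per_dose.items():
                if not 0.0 < m < 1.0:
                    raise ValueError(
                        "invariant violated: absorption means must lie in (0, 1); "
                        f"class {cls} dose {dose} has {m}"
                    )
        if self.absorption_sd < 0:
            raise ValueError("absorption_sd must be non-negative")
        if not 0 <= self.n_missing_dose <= self.n_subjects:
            raise ValueError("n_missing_dose must lie in [0, n_subjects]")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests.

    ``informative_taxa`` is disjoint from the ambiguous taxa by construction.
    ``taxon_params`` records each taxon's sqrt-abundance mean, sd, and the
    signed per-class shift applied to informative taxa.
    """

    informative_taxa: list
    ambiguous_taxa: list
    subject_classes: pd.Series  # subject id -> {1, -1}
    taxon_params: pd.DataFrame  # index taxon; columns mu, tau, shift
    label_mismatch: pd.Series | None = None  # subject -> bool, set by callers

    def to_json(self) -> str:
        obj = {
            "informative_taxa": list(self.informative_taxa),
            "ambiguous_taxa": list(self.ambiguous_taxa),
            "subject_classes": {str(k): int(v) for k, v in self.subject_classes.items()},
            "taxon_params": {
                str(t): {k: float(v) for k, v in row.items()}
                for t, row in self.taxon_params.iterrows()
            },
        }
        return json.dumps(obj, indent=1, sort_keys=True)


def generate_cohort(spec: CohortSpec) -> tuple[AbundanceTable, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic cohort.

    Returns the abundance table, a tidy calcium table (subject, dose,
    absorption) and the planted ground truth. Identical ``spec.seed`` gives
    bit-identical output.

    Mechanism: per-taxon base abundances come from a lognormal weight vector
    normalized to a composition; each sample's sqrt abundance is drawn as a
    truncated Gaussian around the taxon mean, with informative taxa shifted
    by +/- effect_size/2 (in per-taxon sd units) according to subject class;
    entries are then censored to zero below each taxon's sparsity quantile
    (emulating detection-limit zeros, which makes absence itself mildly
    class-informative for shifted taxa) and rows are renormalized to proper
    compositions.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    n_samples = spec.n_subjects * spec.samples_per_subject
    subjects = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
    sample_ids = [
        f"{s}.{j + 1}" for s in subjects for j in range(spec.samples_per_subject)
    ]
    subject_of = pd.Series(
        np.repeat(subjects, spec.samples_per_subject), index=sample_ids
    )

    # Subject classes: exactly round(fraction * n) responders, random identity.
    n_resp = int(round(spec.responder_fraction * spec.n_subjects))
    order = rng.permutation(spec.n_subjects)
    classes = np.full(spec.n_subjects, -1, dtype=int)
    classes[order[:n_resp]] = 1
    subject_classes = pd.Series(classes, index=subjects)
    d_sample = subject_classes.loc[subject_of].to_numpy()

    # Base composition and per-taxon dispersion on the sqrt scale.
    weights = rng.lognormal(mean=0.0, sigma=_LOGNORMAL_SIGMA, size=spec.n_taxa)
    base = weights / weights.sum()
    mu = np.sqrt(base)
    tau = _SQRT_CV * mu

    # Taxon identities: ambiguous taxa at random positions; informative taxa
    # drawn from the unambiguous remainder (disjoint by construction), and
    # from its prevalent half — rare taxa censored to zero in most samples
    # cannot carry class information.
    positions = rng.permutation(spec.n_taxa)
    ambiguous_pos = np.sort(positions[: spec.n_ambiguous])
    names = np.array([f"Taxon_{i + 1:03d}" for i in range(spec.n_taxa)], dtype=object)
    for k, p in enumerate(ambiguous_pos):
        names[p] = f"Other_{k + 1:02d}"
    unamb = positions[spec.n_ambiguous:]
    eligible = unamb[weights[unamb] >= np.median(weights[unamb])]
    if eligible.size < spec.n_informative:
        eligible = unamb  # tiny cohorts: fall back to any unambiguous taxon
    informative_pos = np.sort(
        rng.choice(eligible, size=spec.n_informative, replace=False)
    )

    # Signed class shift for informative taxa. The first informative taxon is
    # elevated in NON-responders (a Roseburia-like profile); signs alternate
    # thereafter so both directions occur.
    shift = np.zeros(spec.n_taxa)
    signs = np.array([(-1) ** (k + 1) for k in range(spec.n_informative)], dtype=float)
    shift[informative_pos] = signs * spec.effect_size * tau[informative_pos] / 2.0

    # Shared per-subject guild factor: all informative taxa load on it along
    # the class axis, correlating a subject's samples with each other.
    guild_load = np.zeros(spec.n_taxa)
    guild_load[informative_pos] = signs * tau[informative_pos]
    u_subject = rng.normal(0.0, spec.subject_sd, size=spec.n_subjects)
    u_sample = pd.Series(u_subject, index=subjects).loc[subject_of].to_numpy()

    # Host-specific deficits: each non-responder subject deviates strongly on
    # its own few informative taxa (pushed further along its class direction).
    deficit_subject = np.zeros((spec.n_subjects, spec.n_taxa))
    if spec.n_subject_deficits > 0 and spec.effect_size > 0:
        strength = spec.deficit_scale * spec.effect_size
        for i in range(spec.n_subjects):
            if classes[i] == -1:
                hit = rng.choice(
                    informative_pos, size=spec.n_subject_deficits, replace=False
                )
                deficit_subject[i, hit] = -strength * guild_load[hit]
    deficit_sample = deficit_subject[
        np.repeat(np.arange(spec.n_subjects), spec.samples_per_subject)
    ]

    # sqrt abundances: mean mu + d*shift + u*guild load + deficits, >= 0.
    mean_matrix = (
        mu[None, :]
        + d_sample[:, None] * shift[None, :]
        + u_sample[:, None] * guild_load[None, :]
        + deficit_sample
    )
    s = rng.normal(loc=mean_matrix, scale=tau[None, :], size=(n_samples, spec.n_taxa))
    np.clip(s, 0.0, None, out=s)
    x = s ** 2

    if spec.sparsity > 0:
        # censor below the per-taxon sparsity quantile: zeros land on the
        # smallest draws, so each taxon's zero fraction ~= spec.sparsity while
        # class shifts also show up as differential absence
        thresh = np.quantile(s, spec.sparsity, axis=0)
        mask = s <= thresh[None, :]
        # keep each row's largest pre-censoring entry so no row is annihilated
        keep = np.argmax(x, axis=1)
        mask[np.arange(n_samples), keep] = False
        x[mask] = 0.0

    x /= x.sum(axis=1, keepdims=True)

    table = AbundanceTable(
        data=pd.DataFrame(x, index=sample_ids, columns=names),
        subjects=subject_of,
    )

    # Calcium absorption per subject per dose, consistent with the class.
    records = []
    for subj in subjects:
        cls = int(subject_classes.loc[subj])
        for dose in sorted(spec.absorption_means[cls]):
            val = rng.normal(spec.absorption_means[cls][dose], spec.absorption_sd)
            records.append((subj, dose, float(np.clip(val, 1e-3, 1 - 1e-3))))
    calcium = make_calcium_table(records)
    if spec.n_missing_dose > 0:
        victims = rng.choice(subjects, size=spec.n_missing_dose, replace=False)
        for subj in victims:
            dose = int(rng.choice([10, 20]))
            calcium = calcium[
                ~((calcium["subject"] == subj) & (calcium["dose"] == dose))
            ].reset_index(drop=True)

    truth = SyntheticTruth(
        informative_taxa=[names[p] for p in informative_pos],
        ambiguous_taxa=[names[p] for p in ambiguous_pos],
        subject_classes=subject_classes,
        taxon_params=pd.DataFrame(
            {"mu": mu, "tau": tau, "shift": shift}, index=pd.Index(names, name="taxon")
        ),
    )
    return table, calcium, truth


def spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["absorption_means"] = {
        str(c): {str(k): v for k, v in per.items()}
        for c, per in spec.absorption_means.items()
    }
    return d
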