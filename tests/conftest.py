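import numpy as np
import pytest

from microresp import CohortSpec, expand_labels, filter_ambiguous, generate_cohort


class Cohort:
    """Bundle of one generated cohort plus derived arrays used across tests."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        self.table, self.calcium, self.truth = generate_cohort(spec)
        self.labels = expand_labels(self.truth.subject_classes, self.table.subjects)
        self.d = self.labels.to_array(self.table.data.index)
        self.X = self.table.values()
        self.s1 = filter_ambiguous(self.table)

    @property
    def informative(self):
        return set(self.truth.informative_taxa)

    def taxon_names(self, idx):
        return set(self.table.taxa[i] for i in np.asarray(idx))


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped cohort: 24 subjects x 4 samples, 221 taxa, 19/5 split."""
    return Cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """Same shape but no class signal (effect_size = 0)."""
    return Cohort(CohortSpec(seed=2, effect_size=0.0))


@pytest.fixture(scope="session")
def strong_cohort():
    """Small, strongly separated cohort for qualitative signal tests."""
    spec = CohortSpec(
        seed=3, n_taxa=60, n_ambiguous=6, n_informative=8,
        effect_size=2.0, sparsity=0.1, subject_sd=0.2, n_subject_deficits=1,
    )
    return Cohort(spec)
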