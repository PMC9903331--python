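import numpy as np
import pytest

from phenodict import (
    CohortSpec,
    DFDLConfig,
    PatchSpec,
    Window,
    composite_from_table,
    default_cohort_spec,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-class cohort with planted Epithelial->CTL coupling in class 1."""
    spec = default_cohort_spec(n_subjects_per_class=6, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_composites(small_cohort):
    return [composite_from_table(t) for t in small_cohort]


def random_unit_dictionary(rng, d, k):
    D = rng.standard_normal((d, k))
    return D / np.linalg.norm(D, axis=0)
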