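import numpy as np
import pytest
from hypothesis import settings

import hippasym as ha

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# z column of the published worked example (right-sided HS patient scored
# against the packaged DRB reference), one decimal, catalogue order:
# 19 subregions then Whole_hippocampal_head, Whole_hippocampal_body,
# Whole_hippocampus.
WORKED_EXAMPLE_Z = {
    "Parasubiculum": -0.9,
    "Presubiculum-Head": -1.9,
    "Subiculum-Head": -2.3,
    "CA1-Head": -5.4,
    "CA2/3-Head": -2.6,
    "CA4-Head": -3.7,
    "GC-ML-DG-head": -3.3,
    "molecular_layer_HP-head": -3.9,
    "HATA": -1.1,
    "Presubiculum-body": -1.8,
    "Subiculum-body": -4.5,
    "CA1-Body": -3.1,
    "CA2/3-body": -3.1,
    "CA4-body": -5.2,
    "GC-ML-DG-body": -4.7,
    "molecular_layer_HP-body": -4.0,
    "fimbria": -0.5,
    "Hippocampal_tail": -3.5,
    "hippocampal-fissure": -1.2,
    "Whole_hippocampal_head": -5.2,
    "Whole_hippocampal_body": -6.5,
    "Whole_hippocampus": -6.3,
}


@pytest.fixture(scope="session")
def hierarchy():
    return ha.canonical_hierarchy()


@pytest.fixture(scope="session")
def drb_reference():
    return ha.packaged_reference("T2_TSE_DRB")


@pytest.fixture(scope="session")
def tse_reference():
    return ha.packaged_reference("T2_TSE")


@pytest.fixture(scope="session")
def worked_example():
    return ha.load_worked_example()


@pytest.fixture(scope="session")
def worked_sides():
    return ha.worked_example_side_volumes()


@pytest.fixture(scope="session")
def healthy_cohort():
    """A 20-control synthetic cohort at the calibrated defaults."""
    return ha.simulate_cohort(ha.default_cohort_spec(n_healthy=20, seed=1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
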