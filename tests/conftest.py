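import pytest

from netpharm.datasets import load_cbeo_contents, load_cbeo_topology
from netpharm.synth_data import generate_study
from netpharm.target_sets import intersect, merge_disease_targets


@pytest.fixture(scope="session")
def cbeo_contents():
    return load_cbeo_contents()


@pytest.fixture(scope="session")
def cbeo_topology():
    return load_cbeo_topology()


@pytest.fixture(scope="session")
def study():
    """One study-scale synthetic input set, shared across tests."""
    return generate_study(seed=1)


@pytest.fixture(scope="session")
def study_overlap(study):
    disease = merge_disease_targets(study.disease_sources, study.filters)
    return intersect(study.compound_map, disease)
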