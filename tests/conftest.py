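import pytest

from ppiscore.integration import merge_sources
from ppiscore.io_formats import default_technique_scores
from ppiscore.model import DEFAULT_PARAMS
from ppiscore.scoring import score_network
from ppiscore.synthetic import SyntheticSpec, generate_sources


@pytest.fixture(scope="session")
def table():
    return default_technique_scores()


def tiny_spec(seed: int, **overrides) -> SyntheticSpec:
    """A small, fast fixture spec for property sweeps over many seeds."""
    kw = dict(n_proteins=40, n_interactions=60, n_studies=8, seed=seed)
    kw.update(overrides)
    return SyntheticSpec(**kw)


@pytest.fixture(scope="session")
def std_data():
    """One standard-conditions synthetic dataset, shared across tests."""
    return generate_sources(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def std_network(std_data, table):
    merged = merge_sources(
        std_data.datasets, std_data.ortholog_records, std_data.mapping
    )
    return score_network(merged.interactions, DEFAULT_PARAMS, table)
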