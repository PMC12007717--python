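import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kinsites.extract import aggregate_sites
from kinsites.simulate import SimConfig, simulate, table1_fixture


@pytest.fixture(scope="session")
def table1():
    """Aggregated sites + raw tables for the published 12-site comparison."""
    proteins, tables, site_list = table1_fixture()
    records = [r for s in sorted(tables) for r in tables[s]]
    sites, skipped = aggregate_sites(records, proteins)
    assert not skipped
    return {
        "proteins": proteins,
        "tables": tables,
        "site_list": site_list,
        "sites": sites,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic synthetic dataset shared across tests."""
    config = SimConfig(
        seed=7,
        n_proteins=10,
        protein_length=(150, 400),
        n_sites={"Mps1": 8, "Ipl1": 5, "Cdk1": 4, "Other": 6},
        n_decoy_lowpsm=3,
        n_decoy_lowconf=3,
    )
    return simulate(config)
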