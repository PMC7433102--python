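import pytest
from hypothesis import settings

from thermsds import Phylogeny, SimConfig, simulate_study, simulate_tree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tree40():
    """A fixed 40-tip ultrametric tree of depth 1."""
    return simulate_tree(40, seed=101)


@pytest.fixture(scope="session")
def tree5():
    """Small hand-checkable 5-tip tree."""
    return Phylogeny.from_newick(
        "((A:0.3,B:0.3):0.7,((C:0.4,D:0.4):0.2,E:0.6):0.4);"
    )


@pytest.fixture(scope="session")
def star50():
    return Phylogeny.star([f"s{i:02d}" for i in range(50)])


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SimConfig(n_species=60, grid_rows=16, grid_cols=16, seed=42,
                    target_transitions=5)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_records(small_study):
    from thermsds import assemble_records

    records, excl = assemble_records(
        small_study.traits, small_study.tree, small_study.grid_temp,
        small_study.grid_precip, small_study.masks,
    )
    assert not excl
    return records
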