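import pytest

from synortho.pipeline import run_census_pipeline
from synortho.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def basic_fixture():
    """Six genomes, default divergence, no deletions."""
    cfg = SimulationConfig(n_genomes=6, seed=11)
    genomes, truth = simulate(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def deletion_result(deletion_fixture):
    """Census pipeline output on the deletion fixture (computed once)."""
    _, genomes, truth = deletion_fixture
    refs = {"egt": truth.ancestor_egt, "Bm9": truth.ancestor_bm9}
    return run_census_pipeline(genomes, refs, truth.seed_gene)


@pytest.fixture(scope="session")
def deletion_fixture():
    """Ten genomes: one member deletion, two Bm9 deletions."""
    cfg = SimulationConfig(
        n_genomes=10,
        seed=7,
        delete_member_in=("NPV06",),
        delete_bm9_in=("NPV02", "NPV08"),
    )
    genomes, truth = simulate(cfg)
    return cfg, genomes, truth
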