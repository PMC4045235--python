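import networkx as nx
import pytest

from interomix import IdentifierPolicy, InteractionDB, SimConfig, simulate_all


@pytest.fixture(scope="session")
def policy():
    return IdentifierPolicy()


@pytest.fixture(scope="session")
def tiny_db():
    """Five-node reference graph used by the hand-enumerated examples."""
    return InteractionDB.from_edges(
        [
            ("A", "B", "physical"),
            ("B", "C", "physical"),
            ("C", "D", "genetic"),
            ("A", "C", "both"),
            ("D", "E", "physical"),
        ],
        label="tiny",
    )


@pytest.fixture(scope="session")
def small_sim():
    """A fast, small synthetic dataset with full ground truth."""
    config = SimConfig(
        n_genes=300, module_size=25, contaminant_pool=40, noise_preys_per_bait=30,
        n_distractor_de=15, n_gene_sets=20, set_size_range=(5, 15), rng_seed=7,
    )
    return simulate_all(config)


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g
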