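import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from linedti.network import HeteroGraph
from linedti.synthetic import SyntheticConfig, generate_dataset


def protein_graph(edges, nodes=None):
    """Small single-type graph from (a, b[, w]) tuples; test helper."""
    g = HeteroGraph()
    names = set(nodes or [])
    for e in edges:
        names.update(e[:2])
    for n in sorted(names):
        g.add_node(n, "protein")
    for e in edges:
        g.add_edge(*e)
    return g


@pytest.fixture
def triangle():
    return protein_graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star4():
    return protein_graph([("hub", leaf) for leaf in ("l1", "l2", "l3", "l4")])


@pytest.fixture
def two_cliques():
    edges = []
    names = [f"n{i:02d}" for i in range(20)]
    for c in (0, 1):
        block = names[10 * c : 10 * c + 10]
        edges.extend(
            (block[i], block[j]) for i in range(10) for j in range(i + 1, 10)
        )
    return protein_graph(edges), names


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (260 nodes, both signals, 5% noise)."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Scaled-down dataset for fast end-to-end smoke tests."""
    return generate_dataset(
        SyntheticConfig(
            n_drugs=10, n_proteins=20, n_lncrna=15, n_mirna=15, n_disease=20,
            n_blocks=4, seed=5,
        )
    )
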