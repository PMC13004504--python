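import networkx as nx
import numpy as np
import pytest

from rewirelab import (
    SequenceSpec,
    configuration_model,
    giant_component,
    synth_degree_sequence,
    toy_graph,
)

# profile mirroring a mid-sized school contact network: n=150, mean degree 5.5,
# degree Gini 0.25 — the workhorse sequence for the rewiring tests
N150_SPEC = SequenceSpec(n=150, mean_degree=5.5, gini=0.25, family="lognormal", name="school150")


@pytest.fixture(scope="session")
def n150_sequence():
    return synth_degree_sequence(N150_SPEC, np.random.default_rng(0))


@pytest.fixture(scope="session")
def n150_network(n150_sequence):
    net = giant_component(configuration_model(n150_sequence, np.random.default_rng(0)))
    assert nx.is_connected(net)
    return net


def fresh_n150_network(n150_sequence, replicate: int) -> nx.Graph:
    """A fresh configuration-model giant from the shared sequence."""
    rng = np.random.default_rng(10_000 + replicate)
    return giant_component(configuration_model(n150_sequence, rng))


@pytest.fixture
def triangle():
    return toy_graph("triangle")


@pytest.fixture
def path3():
    return toy_graph("path3")
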