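import numpy as np
import pandas as pd
import networkx as nx
import pytest

from coabnet import synthdata


@pytest.fixture(scope="session")
def three_stage_counts():
    """Small 3-stage table with one strong conserved pair (0,1) and one
    sign-flipping pair (2,3)."""
    spec = synthdata.PlantedNetworkSpec(
        n_taxa=12,
        stages=("A", "B", "C"),
        conserved_edges=(((0, 1), 0.8),),
        variable_edges=(((2, 3), (0.7, -0.7, 0.7)),),
    )
    mats, truth = synthdata.generate_stage_correlations(spec, seed=11)
    counts = synthdata.generate_counts(mats, n_samples=200, depth=20_000, seed=11)
    return spec, mats, counts, truth


@pytest.fixture
def toy_network():
    """Signed 6-node network: a positive triangle, a negative bridge, a
    pendant."""
    g = nx.Graph(stage="toy")
    edges = [
        ("a", "b", 0.6),
        ("b", "c", 0.5),
        ("a", "c", 0.4),
        ("c", "d", -0.5),
        ("d", "e", 0.7),
        ("e", "f", 0.3),
    ]
    for u, v, r in edges:
        g.add_edge(u, v, r=r, p=0.001, q=0.01)
    for n in g.nodes:
        g.nodes[n]["mean_abundance"] = 1.0
        g.nodes[n]["beneficial"] = n in {"a", "d"}
    return g


def star_graph(n_leaves: int, r: float = 0.5) -> nx.Graph:
    g = nx.Graph()
    for i in range(n_leaves):
        g.add_edge("hub", f"leaf{i}", r=r, p=0.001, q=0.01)
    return g
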