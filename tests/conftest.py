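import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def triangle():
    return nx.complete_graph(3)


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def c4():
    return nx.cycle_graph(4)


@pytest.fixture
def random_graphs():
    """A mix of connected and disconnected sparse random graphs, <= 25 nodes."""
    rng = np.random.default_rng(20240901)
    graphs = []
    for _ in range(12):
        n = int(rng.integers(5, 26))
        p = float(rng.uniform(0.08, 0.35))
        graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return graphs


@pytest.fixture
def tsv_network(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("A\tB\nB\tA\nA\tA\nB\tC\n")
    return p
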