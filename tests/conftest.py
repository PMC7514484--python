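import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from engnet import ThresholdConfig, generate_fixture


@pytest.fixture(scope="session")
def default_thresholds():
    return ThresholdConfig(th1=0.7, th2=0.7, th3=0.7, th_beta=0.8)


@pytest.fixture(scope="session")
def two_module_matrix():
    """Two disjoint 6-gene modules (rho 0.95) plus 50 background genes."""
    return generate_fixture(62, 200, [(6, 0.95), (6, 0.95)], seed=1)


@pytest.fixture
def weighted_square():
    """4-node graph whose maximum spanning tree is known by enumeration."""
    g = nx.Graph()
    g.add_weighted_edges_from(
        [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.5), ("C", "D", 0.7)]
    )
    return g
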