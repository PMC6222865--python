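import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from synstable import GeneNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def gn(edges, nodes=(), validate=True):
    """Shorthand GeneNetwork constructor for tests."""
    return GeneNetwork(edges, nodes=nodes, validate=validate)


def uniform(graph: nx.Graph, w: float) -> GeneNetwork:
    """Wrap a networkx graph with one uniform edge weight."""
    return GeneNetwork((str(a), str(b), w) for a, b in graph.edges)


@pytest.fixture
def path3():
    return gn([("A", "B", 0.8), ("B", "C", 0.8)])


@pytest.fixture
def triangle():
    return gn([("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.7)])


@pytest.fixture
def bowtie():
    # two triangles sharing the cut vertex X, uniform weight
    w = 0.8
    return gn(
        [
            ("A", "B", w),
            ("A", "X", w),
            ("B", "X", w),
            ("C", "D", w),
            ("C", "X", w),
            ("D", "X", w),
        ]
    )
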