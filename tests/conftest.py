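import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from wgdnet.network_build import (
    BIDIRECTIONAL,
    DIRECTIONAL,
    InteractionEdge,
    MetabolicNetwork,
)
from wgdnet.synthetic_data import SyntheticConfig, worked_example_network, generate_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_network(directional=(), bidirectional=(), extra_nodes=()):
    """Small MetabolicNetwork from edge tuples (tests-only convenience)."""
    edges = [InteractionEdge(u, v, DIRECTIONAL) for u, v in directional]
    edges += [
        InteractionEdge(min(u, v), max(u, v), BIDIRECTIONAL) for u, v in bidirectional
    ]
    nodes = {u for e in edges for u in e.endpoints} | set(extra_nodes)
    return MetabolicNetwork(enzymes=nodes, edges=edges)


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_network()


@pytest.fixture(scope="session")
def small_bundle():
    """A complete 120-enzyme synthetic bundle shared across tests."""
    return generate_bundle(SyntheticConfig(seed=11, n_enzymes=120, target_edges=300))


@pytest.fixture(scope="session")
def two_triangles():
    """Two triangles bridged by one edge; optimal split is the triangles."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


@pytest.fixture(scope="session")
def clique_ring():
    """Ring of four triangles; the planted partition is the four triangles."""
    g = nx.Graph()
    for c in range(4):
        base = 3 * c
        g.add_edges_from(
            [(base, base + 1), (base + 1, base + 2), (base, base + 2)]
        )
    for c in range(4):
        g.add_edge(3 * c + 2, (3 * c + 3) % 12)
    planted = {3 * c + i: c for c in range(4) for i in range(3)}
    return g, planted


def partition_groups(assignment):
    groups = {}
    for v, m in assignment.items():
        groups.setdefault(m, set()).add(v)
    return sorted((frozenset(g) for g in groups.values()), key=sorted)


def set_partitions(items):
    """All set partitions of a small collection (exhaustive oracle helper)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1 :]
        yield partial + [{first}]
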