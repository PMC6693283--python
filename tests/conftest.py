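import numpy as np
import pytest

from netdyn import ExpressionSeries, TemporalNetwork
from netdyn.fixtures import FixtureSpec, build_fixture


@pytest.fixture
def triangle_net() -> TemporalNetwork:
    """Directed triangle A->B, A->C, B->C (one frame)."""
    return TemporalNetwork.from_edges([("A", "B"), ("A", "C"), ("B", "C")])


@pytest.fixture
def chain_net() -> TemporalNetwork:
    """Directed chain A->B->C->D (one frame)."""
    return TemporalNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def two_frame_net() -> TemporalNetwork:
    return TemporalNetwork.from_frame_edges(
        {"day1": [("A", "B"), ("B", "C")], "day2": [("B", "C"), ("C", "D")]}
    )


@pytest.fixture
def small_expr() -> ExpressionSeries:
    return ExpressionSeries.from_dict(
        {"TLR4": [0.1, -1.2, -0.4], "CXCL2": [0.0, 0.3, -3.0], "CCL4": [1.5, 2.0, 0.2]},
        frames=["T2", "T8", "T24"],
    )


@pytest.fixture(scope="session")
def session_fixture():
    """One medium synthetic data set shared across read-only tests."""
    return build_fixture(FixtureSpec(seed=11))


def random_digraph(n: int, p: float, seed: int) -> TemporalNetwork:
    """Random directed network (no self-loops) as a single-frame net."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (u, v) for u in nodes for v in nodes if u != v and rng.random() < p
    ]
    return TemporalNetwork.from_edges(edges, nodes=nodes)


def naive_degree_scan(net: TemporalNetwork, frame: str) -> dict[str, tuple[int, int, int]]:
    """Independent O(V*E) oracle: count inner/outer by scanning every edge
    for every node, without touching the analysis module."""
    out: dict[str, tuple[int, int, int]] = {}
    edges = list(net.edges(frame))
    for node in net.nodes:
        inner = sum(1 for _, t in edges if t == node)
        outer = sum(1 for s, _ in edges if s == node)
        out[node] = (inner, outer, inner + outer)
    return out
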