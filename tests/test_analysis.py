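"""Degree decomposition, filtering, neighbourhoods, persistence."""

import pytest

from netdyn import (
    TemporalNetwork,
    degree_over_time,
    degree_table,
    filter_by_degree,
    first_degree_neighbourhood,
    persistence_summary,
    persistent_edges,
)

from conftest import naive_degree_scan, random_digraph


# ----------------------------------------------------------------------
# degree_table
# ----------------------------------------------------------------------
def test_degree_triangle(triangle_net):
    table = degree_table(triangle_net, "frame1")
    assert table.loc["C", ["inner", "outer", "total"]].tolist() == [2, 0, 2]
    assert table.loc["A", ["inner", "outer", "total"]].tolist() == [0, 2, 2]
    assert table.loc["B", ["inner", "outer", "total"]].tolist() == [1, 1, 2]


def test_degree_empty_frame():
    net = TemporalNetwork(["A", "B"], ["f1"], {"f1": {}})
    table = degree_table(net, "f1")
    assert (table[["inner", "outer", "total"]] == 0).all().all()


def test_degree_unknown_frame_is_key_error(triangle_net):
    with pytest.raises(KeyError):
        degree_table(triangle_net, "nope")


def test_self_loop_adds_one_inner_and_one_outer():
    net = TemporalNetwork.from_edges([("A", "A"), ("A", "B")])
    table = degree_table(net, "frame1")
    assert table.loc["A"].tolist() == [1, 2, 3]  # inner, outer, total


def test_undirected_degree_is_incident_edge_count():
    net = TemporalNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("C", "C")], directed=False
    )
    table = degree_table(net, "frame1")
    assert table.loc["B"].tolist() == [2, 2, 2]
    assert table.loc["C"].tolist() == [2, 2, 2]  # one edge to B + the loop


@pytest.mark.parametrize("seed", range(10))
def test_degrees_match_naive_edge_scan_oracle(seed):
    net = random_digraph(n=30, p=0.2, seed=seed)
    table = degree_table(net, "frame1")
    oracle = naive_degree_scan(net, "frame1")
    for node, (inner, outer, total) in oracle.items():
        assert table.loc[node].tolist() == [inner, outer, total]


@pytest.mark.parametrize("seed", range(20))
def test_degree_identities_and_handshake(seed):
    """total = inner + outer per node; sum(inner) = sum(outer) = |E|."""
    net = random_digraph(n=40, p=0.1, seed=100 + seed)
    table = degree_table(net, "frame1")
    assert (table["total"] == table["inner"] + table["outer"]).all()
    m = net.n_edges("frame1")
    assert table["inner"].sum() == m
    assert table["outer"].sum() == m


# ----------------------------------------------------------------------
# degree_over_time
# ----------------------------------------------------------------------
def test_degree_over_time_tracks_edge_appearance():
    net = TemporalNetwork.from_frame_edges(
        {"f1": [("C", "D")], "f2": [("A", "B"), ("C", "D")]}
    )
    tidy = degree_over_time(net)
    a = tidy[tidy.node == "A"].set_index("frame")
    assert a.loc["f1", "total"] == 0
    assert a.loc["f2", "total"] == 1


def test_degree_over_time_static_network_constant(triangle_net):
    replicated = triangle_net.replicate_frames(["t1", "t2", "t3"])
    tidy = degree_over_time(replicated)
    pivot = tidy.pivot(index="node", columns="frame", values="total")
    assert (pivot.nunique(axis=1) == 1).all()


def test_planted_hub_degree_is_strictly_increasing():
    spokes = [2, 5, 9]
    frames = [f"f{i}" for i in range(3)]
    frame_edges = {
        frame: [(f"s{j}", "H") for j in range(k)]
        for frame, k in zip(frames, spokes)
    }
    net = TemporalNetwork.from_frame_edges(frame_edges, frame_order=frames)
    tidy = degree_over_time(net)
    hub = tidy[tidy.node == "H"].sort_values("frame")["total"].tolist()
    assert hub == spokes
    assert all(b > a for a, b in zip(hub, hub[1:]))


# ----------------------------------------------------------------------
# filter_by_degree
# ----------------------------------------------------------------------
def test_filter_threshold_zero_is_identity(triangle_net):
    sub = filter_by_degree(triangle_net, "frame1", 0)
    assert set(sub.nodes) == set(triangle_net.nodes)
    assert sub.edge_set() == triangle_net.edges("frame1")


def test_filter_threshold_two_on_triangle(triangle_net):
    # totals: A=2, B=2, C=2 minus B? A->B, A->C, B->C: A(0,2) B(1,1) C(2,0)
    sub = filter_by_degree(triangle_net, "frame1", 2, which="inner")
    assert set(sub.nodes) == {"C"}
    assert sub.edge_set() == set()


def test_filter_retains_edges_between_survivors():
    net = TemporalNetwork.from_edges(
        [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")]
    )
    sub = filter_by_degree(net, "frame1", 2, which="total")
    assert set(sub.nodes) == {"A", "B", "C"}
    assert sub.edge_set() == {("A", "B"), ("A", "C"), ("B", "C")}


def test_filter_above_max_degree_empties(triangle_net):
    sub = filter_by_degree(triangle_net, "frame1", 99)
    assert sub.nodes == []
    assert sub.edge_set() == set()


def test_filter_negative_threshold_errors(triangle_net):
    with pytest.raises(ValueError):
        filter_by_degree(triangle_net, "frame1", -1)


@pytest.mark.parametrize("seed", range(5))
def test_filter_is_monotone_in_threshold(seed):
    net = random_digraph(n=25, p=0.15, seed=200 + seed)
    previous = None
    for threshold in range(0, 8):
        sub = filter_by_degree(net, "frame1", threshold)
        nodes = set(sub.nodes)
        if previous is not None:
            assert nodes <= previous
        assert sub.edge_set() <= net.edges("frame1")
        previous = nodes


# ----------------------------------------------------------------------
# first_degree_neighbourhood
# ----------------------------------------------------------------------
def test_neighbourhood_of_chain_middle(chain_net):
    sub = first_degree_neighbourhood(chain_net, "B", "frame1")
    assert set(sub.nodes) == {"A", "B", "C"}
    assert sub.edge_set() == {("A", "B"), ("B", "C")}
    assert sub.focus == "B"


def test_neighbourhood_of_isolated_node():
    net = TemporalNetwork(["A", "B", "X"], ["f1"], {"f1": {("A", "B"): None}})
    sub = first_degree_neighbourhood(net, "X", "f1")
    assert sub.nodes == ["X"]
    assert sub.edge_set() == set()


def test_neighbourhood_unknown_node_key_error(chain_net):
    with pytest.raises(KeyError):
        first_degree_neighbourhood(chain_net, "Z", "frame1")


def test_neighbourhood_includes_edges_among_neighbours():
    net = TemporalNetwork.from_edges(
        [("A", "H"), ("H", "B"), ("A", "B"), ("C", "D")]
    )
    sub = first_degree_neighbourhood(net, "H", "frame1")
    assert set(sub.nodes) == {"A", "B", "H"}
    assert sub.edge_set() == {("A", "H"), ("H", "B"), ("A", "B")}


@pytest.mark.parametrize("seed", range(5))
def test_neighbourhood_contains_focus_and_subsets_parent(seed):
    net = random_digraph(n=20, p=0.15, seed=300 + seed)
    for node in net.nodes[:5]:
        sub = first_degree_neighbourhood(net, node, "frame1")
        assert node in sub.nodes
        assert sub.edge_set() <= net.edges("frame1")


# ----------------------------------------------------------------------
# persistent_edges
# ----------------------------------------------------------------------
def test_persistence_same_frame_is_idempotent(two_frame_net):
    assert persistent_edges(two_frame_net, "day1", "day1") == two_frame_net.edges(
        "day1"
    )


def test_persistence_intersection(two_frame_net):
    assert persistent_edges(two_frame_net, "day1", "day2") == {("B", "C")}


def test_persistence_summary_counts(two_frame_net):
    summary = persistence_summary(two_frame_net, "day1", "day2")
    assert summary == {
        "edges_a": 2,
        "edges_b": 2,
        "persistent": 1,
        "lost": 1,
        "gained": 1,
    }


def test_persistence_ignores_relation_tokens():
    net = TemporalNetwork.from_frame_edges(
        {"f1": [("A", "B", "pp")], "f2": [("A", "B", "pd")]}
    )
    assert persistent_edges(net, "f1", "f2") == {("A", "B")}
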