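"""Degree analytics, threshold filtering, neighbourhoods, edge persistence.

Degree centrality is split into three components: *inner* degree (edges
pointing into a node — the node is regulated by many neighbours), *outer*
degree (edges pointing out — the node regulates many others) and *total*
degree, their sum.  Nodes with high degree are hub candidates; biological
networks tolerate random perturbations but fail when such pivotal nodes
are disrupted, which is why the degree decomposition and the threshold
filter exist.

Conventions (directed networks): a self-loop contributes 1 to inner and
1 to outer (hence 2 to total).  For undirected networks the inner/outer
split is not meaningful: inner = outer = total = number of incident
edges (a self-loop counts once).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import EdgeKey, Subnetwork, TemporalNetwork

__all__ = [
    "degree_table",
    "degree_over_time",
    "filter_by_degree",
    "first_degree_neighbourhood",
    "persistent_edges",
    "persistence_summary",
    "write_degree_table",
]

DEGREE_KINDS = ("total", "inner", "outer")


def degree_table(net: TemporalNetwork, frame: str) -> pd.DataFrame:
    """Per-node inner/outer/total degree for one frame.

    Returns a DataFrame indexed by node with integer columns ``inner``,
    ``outer`` and ``total``, covering every network node (zeros for nodes
    isolated in this frame).
    """
    graph = net.to_networkx(frame)
    if net.directed:
        inner = dict(graph.in_degree())
        outer = dict(graph.out_degree())
        table = pd.DataFrame(
            {
                "inner": [inner[v] for v in net.nodes],
                "outer": [outer[v] for v in net.nodes],
            },
            index=pd.Index(net.nodes, name="node"),
        )
        table["total"] = table["inner"] + table["outer"]
    else:
        # incident edge count: networkx counts undirected self-loops twice,
        # the convention here counts the incident edge once
        incident = {v: 0 for v in net.nodes}
        for source, target in net.edges(frame):
            incident[source] += 1
            if target != source:
                incident[target] += 1
        counts = [incident[v] for v in net.nodes]
        table = pd.DataFrame(
            {"inner": counts, "outer": counts, "total": counts},
            index=pd.Index(net.nodes, name="node"),
        )
    return table.astype(int)


def degree_over_time(net: TemporalNetwork) -> pd.DataFrame:
    """Tidy per-frame degree table: columns node, frame, inner, outer, total.

    This is the exportable "node degree table": how the degree of each
    node changes over the frame series, highlighting when a node matters.
    """
    parts = []
    for frame in net.frames:
        part = degree_table(net, frame).reset_index()
        part.insert(1, "frame", frame)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_degree_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = table.reset_index() if table.index.name == "node" else table
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def filter_by_degree(
    net: TemporalNetwork,
    frame: str,
    threshold: int,
    which: str = "total",
) -> Subnetwork:
    """Hide nodes whose chosen degree is below a threshold.

    Retains nodes with ``which``-degree >= threshold in *frame*, plus the
    edges whose both endpoints survive.  Threshold 0 is the identity.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if which not in DEGREE_KINDS:
        raise ValueError(f"degree kind must be one of {DEGREE_KINDS}, got {which!r}")
    degrees = degree_table(net, frame)[which]
    retained = [v for v in net.nodes if degrees[v] >= threshold]
    retained_set = set(retained)
    edges = {
        key: rel
        for key, rel in net.edges_by_frame[frame].items()
        if key[0] in retained_set and key[1] in retained_set
    }
    return Subnetwork(net, frame, retained, edges, provenance="threshold")


def first_degree_neighbourhood(
    net: TemporalNetwork, node: str, frame: str
) -> Subnetwork:
    """The local network around a node: the node, its frame-neighbours in
    either direction, and all frame edges among that set.

    This is the view used to inspect a gene whose expression changes
    sharply — its regulators and targets frame by frame.
    """
    if node not in net.nodes:
        raise KeyError(f"unknown node {node!r}")
    net._check_frame(frame)
    neighbours: set[str] = set()
    for source, target in net.edges(frame):
        if source == node:
            neighbours.add(target)
        if target == node:
            neighbours.add(source)
    neighbours.discard(node)
    retained_set = {node} | neighbours
    retained = [v for v in net.nodes if v in retained_set]
    edges = {
        key: rel
        for key, rel in net.edges_by_frame[frame].items()
        if key[0] in retained_set and key[1] in retained_set
    }
    return Subnetwork(
        net, frame, retained, edges, provenance="neighbourhood", focus=node
    )


def persistent_edges(
    net: TemporalNetwork, frame_a: str, frame_b: str
) -> set[EdgeKey]:
    """Edges present in both frames (e.g. exposure day 3 and washout).

    Edge identity is the ordered (source, target) pair; relation tokens
    are ignored.
    """
    return net.edges(frame_a) & net.edges(frame_b)


def persistence_summary(
    net: TemporalNetwork, frame_a: str, frame_b: str
) -> dict[str, int]:
    """Companion counts for a two-frame comparison:
    |A|, |B|, |A∩B| (persistent), |A\\B| (lost), |B\\A| (gained)."""
    a, b = net.edges(frame_a), net.edges(frame_b)
    return {
        "edges_a": len(a),
        "edges_b": len(b),
        "persistent": len(a & b),
        "lost": len(a - b),
        "gained": len(b - a),
    }
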