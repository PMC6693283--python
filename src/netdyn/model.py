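"""Core data model: temporal networks, expression series, subnetworks.

A *temporal network* is a fixed node set plus an ordered list of frames
(time points, doses, or dose-over-time combinations), each with its own
edge set.  A static network is the degenerate case with exactly one frame.
Edges are identified by their ordered (source, target) pair; an optional
relation token (as in Cytoscape SIF files) rides along but does not
participate in edge identity.  For undirected networks the endpoint pair
is stored in canonical (sorted) order so that (A, B) and (B, A) are the
same edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "DEFAULT_FRAME",
    "TemporalNetwork",
    "ExpressionSeries",
    "Subnetwork",
]

#: Frame label used when a static network is read from a single-frame file.
DEFAULT_FRAME = "frame1"

EdgeKey = tuple[str, str]


def _canonical(source: str, target: str, directed: bool) -> EdgeKey:
    if directed or source <= target:
        return (source, target)
    return (target, source)


@dataclass
class TemporalNetwork:
    """Node set plus per-frame edge sets.

    Parameters
    ----------
    nodes
        Ordered, duplicate-free node identifiers (case-sensitive strings).
    frames
        Ordered frame labels; at least one.
    edges_by_frame
        Frame label -> {(source, target): relation or None}.  Duplicate
        edges within a frame collapse to one; self-loops are retained.
    directed
        Whether edges are ordered pairs.  Biological regulatory networks
        ("A regulates B") are directed, which is the default.
    """

    nodes: list[str]
    frames: list[str]
    edges_by_frame: dict[str, dict[EdgeKey, str | None]]
    directed: bool = True

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a temporal network needs at least one frame")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        node_set = set(self.nodes)
        for frame in self.frames:
            self.edges_by_frame.setdefault(frame, {})
        for frame, edges in self.edges_by_frame.items():
            if frame not in self.frames:
                raise ValueError(f"edge frame {frame!r} not in frame list")
            for source, target in edges:
                if source not in node_set or target not in node_set:
                    raise ValueError(
                        f"edge endpoint not in node set: {(source, target)}"
                    )

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, str | None]],
        *,
        directed: bool = True,
        frame: str = DEFAULT_FRAME,
        nodes: Iterable[str] | None = None,
    ) -> "TemporalNetwork":
        """Build a single-frame network from an edge iterable."""
        edge_map: dict[EdgeKey, str | None] = {}
        seen: dict[str, None] = dict.fromkeys(nodes or [])
        for record in edges:
            source, target = record[0], record[1]
            relation = record[2] if len(record) > 2 else None
            seen.setdefault(source)
            seen.setdefault(target)
            edge_map.setdefault(_canonical(source, target, directed), relation)
        return cls(list(seen), [frame], {frame: edge_map}, directed=directed)

    @classmethod
    def from_frame_edges(
        cls,
        frame_edges: Mapping[str, Iterable[tuple[str, str] | tuple[str, str, str | None]]],
        *,
        directed: bool = True,
        frame_order: list[str] | None = None,
    ) -> "TemporalNetwork":
        """Build a multi-frame network from per-frame edge iterables."""
        frames = frame_order or list(frame_edges)
        missing = set(frame_edges) - set(frames)
        if missing:
            raise ValueError(f"frame order omits labels: {sorted(missing)}")
        seen: dict[str, None] = {}
        by_frame: dict[str, dict[EdgeKey, str | None]] = {}
        for frame in frames:
            edge_map: dict[EdgeKey, str | None] = {}
            for record in frame_edges.get(frame, ()):
                source, target = record[0], record[1]
                relation = record[2] if len(record) > 2 else None
                seen.setdefault(source)
                seen.setdefault(target)
                edge_map.setdefault(_canonical(source, target, directed), relation)
            by_frame[frame] = edge_map
        return cls(list(seen), frames, by_frame, directed=directed)

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    @property
    def is_static(self) -> bool:
        return len(self.frames) == 1

    def edges(self, frame: str) -> set[EdgeKey]:
        """Edge (source, target) pairs active in *frame*."""
        self._check_frame(frame)
        return set(self.edges_by_frame[frame])

    def edge_records(self, frame: str) -> list[tuple[str, str, str | None]]:
        self._check_frame(frame)
        return [(s, t, r) for (s, t), r in self.edges_by_frame[frame].items()]

    def all_edges(self) -> set[EdgeKey]:
        out: set[EdgeKey] = set()
        for frame in self.frames:
            out |= set(self.edges_by_frame[frame])
        return out

    def n_edges(self, frame: str) -> int:
        self._check_frame(frame)
        return len(self.edges_by_frame[frame])

    def to_networkx(self, frame: str) -> "nx.DiGraph | nx.Graph":
        """The frame's graph as a networkx (Di)Graph, nodes included even
        when isolated in this frame."""
        self._check_frame(frame)
        graph = nx.DiGraph() if self.directed else nx.Graph()
        graph.add_nodes_from(self.nodes)
        for (source, target), relation in self.edges_by_frame[frame].items():
            graph.add_edge(source, target, relation=relation)
        return graph

    def replicate_frames(self, frames: list[str]) -> "TemporalNetwork":
        """Replicate a static network's edge set over new frame labels.

        Used when a static network is animated against a multi-frame
        expression series: the topology is constant, only colours change.
        """
        if not self.is_static:
            raise ValueError("only a static network can be replicated over frames")
        base = self.edges_by_frame[self.frames[0]]
        return TemporalNetwork(
            list(self.nodes),
            list(frames),
            {f: dict(base) for f in frames},
            directed=self.directed,
        )

    def _check_frame(self, frame: str) -> None:
        if frame not in self.edges_by_frame:
            raise KeyError(f"unknown frame {frame!r}; frames are {self.frames}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "directed" if self.directed else "undirected"
        return (
            f"TemporalNetwork({len(self.nodes)} nodes, "
            f"{len(self.frames)} frame(s), {kind})"
        )


class ExpressionSeries:
    """Node x frame matrix of expression values in user units.

    Values may be intensities or log fold changes; the unit is opaque to
    the engine.  Missing cells are NaN (absent, not zero) and render in
    the neutral missing-data colour downstream.
    """

    def __init__(self, table: pd.DataFrame):
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated node id(s) in expression table: {dups}")
        self._table = table.astype(float)

    @classmethod
    def from_dict(
        cls, values: Mapping[str, Iterable[float]], frames: list[str]
    ) -> "ExpressionSeries":
        return cls(pd.DataFrame.from_dict(values, orient="index", columns=frames))

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def nodes(self) -> list[str]:
        return list(self._table.index)

    @property
    def frames(self) -> list[str]:
        return [str(c) for c in self._table.columns]

    def value(self, node: str, frame: str) -> float | None:
        """Value for (node, frame); None when the node is absent from the
        table or the cell is missing."""
        if node not in self._table.index:
            return None
        cell = self._table.at[node, frame]
        return None if pd.isna(cell) else float(cell)

    def max_abs(self) -> float:
        values = self._table.to_numpy(dtype=float)
        finite = values[~pd.isna(values)]
        if finite.size == 0:
            raise ValueError("expression series has no numeric values")
        return float(abs(finite).max())

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (node, frame, value) table; missing cells dropped."""
        tidy = (
            self._table.rename_axis("node")
            .reset_index()
            .melt(id_vars="node", var_name="frame", value_name="value")
            .dropna(subset=["value"])
        )
        order = {f: i for i, f in enumerate(self.frames)}
        return (
            tidy.assign(_o=tidy["frame"].map(order))
            .sort_values(["node", "_o"], kind="stable")
            .drop(columns="_o")
            .reset_index(drop=True)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionSeries({len(self.nodes)} nodes x {len(self.frames)} frames)"


@dataclass
class Subnetwork:
    """A node/edge selection from one frame of a parent network.

    Invariant: retained edges are a subset of the parent frame's edges and
    both endpoints of every retained edge are retained nodes.
    """

    parent: TemporalNetwork
    frame: str
    nodes: list[str]
    edges: dict[EdgeKey, str | None]
    provenance: str  # "threshold" | "neighbourhood"
    focus: str | None = None
    _parent_edges: set[EdgeKey] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._parent_edges = self.parent.edges(self.frame)
        retained = set(self.nodes)
        for source, target in self.edges:
            if (source, target) not in self._parent_edges:
                raise ValueError("retained edge not present in parent frame")
            if source not in retained or target not in retained:
                raise ValueError("retained edge endpoint not retained")

    def edge_set(self) -> set[EdgeKey]:
        return set(self.edges)

    def to_network(self) -> TemporalNetwork:
        """The selection as a standalone single-frame network."""
        return TemporalNetwork(
            list(self.nodes),
            [self.frame],
            {self.frame: dict(self.edges)},
            directed=self.parent.directed,
        )

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)
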