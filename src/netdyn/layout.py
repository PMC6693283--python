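"""Deterministic force-directed 2D layout and the 3D z-extension.

The 2D layout is a Fruchterman–Reingold spring embedding: every pair of
nodes repels with force ``k^2 / d`` and every edge attracts with force
``d^2 / k``, where ``d`` is the current pair distance and ``k`` the
natural spring length.  Displacements are capped by a temperature that
cools geometrically, so the embedding settles.  For two connected nodes
the forces balance exactly at ``d = k``, which anchors the constants.

Constants (dimensionless, unit-square scale):
    natural length k   sqrt(1/n) by default (area-equipartition heuristic)
    initial temperature 0.1, cooling factor 0.97 per sweep
    iteration cap      300 sweeps

The third dimension is a closed-form lift of the normalized 2D layout:

    z = 0.8 * y * sin(pi * y) + 0.8 * x * sin(pi * x)

for x, y in [0, 1].  z vanishes on the layout corners and peaks in the
centre, folding the flat layout into a dome that can be navigated or
exported; |z| <= 0.8 * (x + y) <= 1.6 everywhere on the unit square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TemporalNetwork

__all__ = [
    "LayoutPosition",
    "force_directed_2d",
    "extend_to_3d",
    "z_value",
    "write_layout",
]

INITIAL_TEMPERATURE = 0.1
COOLING_FACTOR = 0.97
DEFAULT_ITERATIONS = 300
_EPS = 1e-9


@dataclass
class LayoutPosition:
    """Per-node coordinates; x and y normalized to [0, 1] per axis."""

    coords: dict[str, tuple[float, ...]]

    @property
    def dimensions(self) -> int:
        return len(next(iter(self.coords.values()))) if self.coords else 0

    def __getitem__(self, node: str) -> tuple[float, ...]:
        return self.coords[node]

    def __contains__(self, node: str) -> bool:
        return node in self.coords

    def to_frame(self) -> pd.DataFrame:
        columns = ["x", "y", "z"][: self.dimensions]
        return pd.DataFrame.from_dict(
            self.coords, orient="index", columns=columns
        ).rename_axis("node")

    def to_json_block(self) -> dict[str, list[float]]:
        return {node: list(map(float, xy)) for node, xy in self.coords.items()}


def _normalize(array: np.ndarray) -> np.ndarray:
    """Min-max rescale each axis to [0, 1]; a degenerate axis maps to 0.5."""
    out = np.empty_like(array)
    for axis in range(array.shape[1]):
        column = array[:, axis]
        span = column.max() - column.min()
        if span < _EPS:
            out[:, axis] = 0.5
        else:
            out[:, axis] = (column - column.min()) / span
    return out


def force_directed_2d(
    net: TemporalNetwork,
    frame: str | None = None,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    *,
    natural_length: float | None = None,
    normalize: bool = True,
) -> LayoutPosition:
    """Spring-embed one frame (or, with ``frame=None``, the union of all
    frames, so positions stay fixed across an animation).

    Deterministic given (network, frame, iterations, seed): initial
    positions are drawn for nodes in sorted order, so the result does not
    depend on node input order.

    Parameters
    ----------
    iterations
        Number of force sweeps (>= 1).
    seed
        Seeds the initial random placement.
    natural_length
        Spring rest length k; default sqrt(1/n).
    normalize
        Min-max rescale the final coordinates to [0, 1] per axis
        (the form the z-extension and all exports expect).  Disable to
        inspect raw equilibrium geometry.
    """
    if not net.nodes:
        raise ValueError("cannot lay out an empty network")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if frame is None:
        edge_keys = net.all_edges()
    else:
        edge_keys = net.edges(frame)
    # layout treats the graph as undirected; self-loops exert no force
    edges = np.array(
        sorted(
            {
                (min(index[s], index[t]), max(index[s], index[t]))
                for s, t in edge_keys
                if s != t
            }
        ),
        dtype=int,
    ).reshape(-1, 2)

    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    if n == 1:
        return LayoutPosition({nodes[0]: (0.5, 0.5)})

    k = natural_length if natural_length is not None else float(np.sqrt(1.0 / n))
    temperature = INITIAL_TEMPERATURE
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]  # (n, n, 2)
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, _EPS)
        # repulsion k^2 / d, directed away from every other node
        repulse = (k * k) / dist
        np.fill_diagonal(repulse, 0.0)
        disp = (delta / dist[..., None] * repulse[..., None]).sum(axis=1)
        # attraction d^2 / k along each edge
        if edges.size:
            i, j = edges[:, 0], edges[:, 1]
            evec = pos[j] - pos[i]
            edist = np.maximum(np.linalg.norm(evec, axis=1, keepdims=True), _EPS)
            pull = evec / edist * (edist**2 / k)
            np.add.at(disp, i, pull)
            np.add.at(disp, j, -pull)
        length = np.maximum(np.linalg.norm(disp, axis=1, keepdims=True), _EPS)
        pos += disp / length * np.minimum(length, temperature)
        temperature *= COOLING_FACTOR

    if normalize:
        pos = _normalize(pos)
    return LayoutPosition({v: (float(x), float(y)) for v, (x, y) in zip(nodes, pos)})


def z_value(x: float, y: float) -> float:
    """The dome lift for a normalized 2D point."""
    return 0.8 * y * float(np.sin(np.pi * y)) + 0.8 * x * float(np.sin(np.pi * x))


def extend_to_3d(pos: LayoutPosition) -> LayoutPosition:
    """Add the z coordinate to a normalized 2D layout; x and y unchanged.

    Raises ``ValueError`` when the input is not normalized to [0, 1]
    (the formula is only defined on the unit square).
    """
    coords: dict[str, tuple[float, ...]] = {}
    for node, point in pos.coords.items():
        x, y = point[0], point[1]
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(
                f"node {node!r} has non-normalized coordinates ({x}, {y}); "
                "extend_to_3d expects x, y in [0, 1]"
            )
        coords[node] = (x, y, z_value(x, y))
    return LayoutPosition(coords)


def write_layout(pos: LayoutPosition, path: str | Path, *, as_json: bool = False) -> Path:
    """Write positions as TSV (node, x, y[, z]) or as a JSON layout block."""
    path = Path(path)
    if as_json:
        path.write_text(
            json.dumps(pos.to_json_block(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    else:
        pos.to_frame().to_csv(path, sep="\t", lineterminator="\n")
    return path
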