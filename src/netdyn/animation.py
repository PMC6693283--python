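"""Frame-by-frame animation assembly and export.

An :class:`Animation` is an ordered list of fully-resolved frames — node
positions, colours, radii, active edges and per-frame degrees — that can
be stepped forward/backward like the in-browser player, or exported as a
GIF, a numbered PNG sequence, a single-frame SVG, or a self-contained
HTML page with stepping controls.  Node positions are fixed across
frames by default so that frames are visually comparable: the animation
recolours and rewires, it does not re-lay-out.

Two animation modes compose freely:

* node-expression animation — a static network whose node colours follow
  a multi-frame expression series;
* edge-interaction animation — a dynamic edge set (edges appear and
  disappear per frame), with or without expression colouring on top.

Nodes with no incident edge in a frame remain drawn, greyed out, so the
layout stays comparable; ``drop_absent=True`` removes them instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from PIL import Image

from .analysis import degree_over_time, degree_table
from .layout import LayoutPosition, force_directed_2d
from .model import EdgeKey, ExpressionSeries, TemporalNetwork
from .style import (
    MISSING_COLOUR,
    ColourScale,
    SizeRule,
    build_colour_scale,
    colour_to_hex,
    degree_to_radius,
    value_to_colour,
)

__all__ = [
    "AnimationFrame",
    "Animation",
    "build_animation",
    "step",
    "export_animation",
    "export_svg",
    "line_graph",
]

logger = logging.getLogger(__name__)

#: node colour when no expression series is supplied
UNIFORM_NODE_COLOUR = "#4682b4"

DEFAULT_FRAME_DURATION_MS = 1000


@dataclass
class AnimationFrame:
    label: str
    positions: LayoutPosition
    colours: dict[str, str]  # node -> #rrggbb
    radii: dict[str, float]
    edges: set[EdgeKey]
    degrees: pd.DataFrame  # indexed by node: inner, outer, total
    absent: set[str] = field(default_factory=set)
    nodes: list[str] = field(default_factory=list)


@dataclass
class Animation:
    frames: list[AnimationFrame]
    cursor: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("animation needs at least one frame")

    @property
    def current(self) -> AnimationFrame:
        return self.frames[self.cursor]

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.frames]

    def __len__(self) -> int:
        return len(self.frames)


def _reconcile(
    net: TemporalNetwork,
    expr: ExpressionSeries | None,
    frame_map: dict[str, str] | None,
) -> tuple[TemporalNetwork, dict[str, str | None]]:
    """Return the network to animate and a map frame label -> expression
    column (None when the frame has no expression)."""
    if expr is None:
        return net, {f: None for f in net.frames}
    if net.is_static and len(expr.frames) > 1:
        net = net.replicate_frames(expr.frames)
        return net, {f: f for f in net.frames}
    mapping: dict[str, str | None] = {}
    expr_frames = set(expr.frames)
    for frame in net.frames:
        column = (frame_map or {}).get(frame, frame)
        if column not in expr_frames:
            raise ValueError(
                "cannot reconcile frame labels: network frames "
                f"{net.frames} vs expression frames {expr.frames}"
                + ("" if frame_map is None else f" with map {frame_map}")
            )
        mapping[frame] = column
    return net, mapping


def build_animation(
    net: TemporalNetwork,
    expr: ExpressionSeries | None = None,
    layout: LayoutPosition | None = None,
    scale: ColourScale | None = None,
    size_rule: SizeRule | None = None,
    *,
    frame_map: dict[str, str] | None = None,
    drop_absent: bool = False,
    seed: int = 0,
) -> Animation:
    """Assemble one resolved frame per network/expression frame.

    Colours come from the expression series through the shared global
    colour scale (identical value -> identical colour in every frame);
    edges come from each frame's edge set; radii follow the frame's
    degrees when the size rule is degree-based.
    """
    net, expr_columns = _reconcile(net, expr, frame_map)
    if layout is None:
        layout = force_directed_2d(net, frame=None, seed=seed)
    if expr is not None and scale is None:
        scale = build_colour_scale(expr)
    if size_rule is None:
        size_rule = SizeRule(mode="fixed")
    if size_rule.degree_kind is not None and size_rule.max_degree == 0:
        observed = int(degree_over_time(net)[size_rule.degree_kind].max())
        size_rule = SizeRule(
            mode=size_rule.mode,
            min_radius=size_rule.min_radius,
            max_radius=size_rule.max_radius,
            max_degree=observed,
        )

    frames: list[AnimationFrame] = []
    for frame in net.frames:
        degrees = degree_table(net, frame)
        active = {v for s, t in net.edges(frame) for v in (s, t)}
        absent = set(net.nodes) - active
        nodes = [v for v in net.nodes if not (drop_absent and v in absent)]
        colours: dict[str, str] = {}
        radii: dict[str, float] = {}
        for node in nodes:
            if expr is None or scale is None:
                colours[node] = UNIFORM_NODE_COLOUR
            else:
                value = expr.value(node, expr_columns[frame])
                colours[node] = colour_to_hex(value_to_colour(scale, value))
            if size_rule.degree_kind is None:
                radii[node] = size_rule.min_radius
            else:
                radii[node] = degree_to_radius(
                    size_rule, int(degrees.at[node, size_rule.degree_kind])
                )
        frames.append(
            AnimationFrame(
                label=frame,
                positions=layout,
                colours=colours,
                radii=radii,
                edges=net.edges(frame),
                degrees=degrees,
                absent=absent if not drop_absent else set(),
                nodes=nodes,
            )
        )
    return Animation(frames=frames)


def step(anim: Animation, direction: str) -> AnimationFrame:
    """Move the cursor one frame forward or backward, clamped at the ends."""
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    delta = 1 if direction == "forward" else -1
    anim.cursor = max(0, min(len(anim.frames) - 1, anim.cursor + delta))
    return anim.current


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------
def _render_frame(frame: AnimationFrame, *, dpi: int = 100) -> np.ndarray:
    fig, ax = plt.subplots(figsize=(5, 5), dpi=dpi)
    try:
        _draw_frame(ax, frame)
        fig.canvas.draw()
        buffer = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
    finally:
        plt.close(fig)
    return buffer


def _draw_frame(ax, frame: AnimationFrame) -> None:
    ax.set_xlim(-0.08, 1.08)
    ax.set_ylim(-0.08, 1.08)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(str(frame.label))
    drawn = set(frame.nodes)
    for source, target in sorted(frame.edges):
        if source not in drawn or target not in drawn:
            continue
        x0, y0 = frame.positions[source][:2]
        x1, y1 = frame.positions[target][:2]
        ax.plot([x0, x1], [y0, y1], color="0.6", linewidth=0.8, zorder=1)
    xs, ys, cs, ss, alphas = [], [], [], [], []
    for node in frame.nodes:
        x, y = frame.positions[node][:2]
        xs.append(x)
        ys.append(y)
        cs.append(frame.colours[node])
        ss.append(frame.radii[node] ** 2)  # scatter sizes are area-like
        alphas.append(0.35 if node in frame.absent else 1.0)
    ax.scatter(xs, ys, c=cs, s=ss, alpha=alphas, edgecolors="black", zorder=2)
    if len(frame.nodes) <= 60:
        for node, x, y in zip(frame.nodes, xs, ys):
            ax.annotate(
                node, (x, y), textcoords="offset points", xytext=(0, 6),
                ha="center", fontsize=6,
            )


def export_svg(frame: AnimationFrame, path: str | Path) -> Path:
    """Render one frame as an SVG file."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 5))
    try:
        _draw_frame(ax, frame)
        fig.savefig(path, format="svg", bbox_inches="tight")
    finally:
        plt.close(fig)
    return path


def export_animation(
    anim: Animation,
    path: str | Path,
    format: str = "gif",
    *,
    duration_ms: int = DEFAULT_FRAME_DURATION_MS,
) -> list[Path]:
    """Export every frame of the animation.

    ``gif``: one animated GIF at *path* (frame count preserved exactly).
    ``png_sequence``: *path* is a directory receiving frame_001.png, ...
    ``html``: a self-contained page at *path* embedding the frame data
    and minimal forward/backward stepping logic (a static artefact).
    """
    path = Path(path)
    if format == "gif":
        images = [Image.fromarray(_render_frame(f)) for f in anim.frames]
        images[0].save(
            path,
            save_all=True,
            append_images=images[1:],
            duration=duration_ms,
            loop=0,
        )
        return [path]
    if format == "png_sequence":
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for number, frame in enumerate(anim.frames, start=1):
            target = path / f"frame_{number:03d}.png"
            Image.fromarray(_render_frame(frame)).save(target)
            written.append(target)
        return written
    if format == "html":
        path.write_text(_html_page(anim), encoding="utf-8")
        return [path]
    raise ValueError(f"unknown export format {format!r}")


def _frame_json(anim: Animation) -> str:
    payload = []
    for frame in anim.frames:
        payload.append(
            {
                "label": frame.label,
                "nodes": [
                    {
                        "id": node,
                        "x": frame.positions[node][0],
                        "y": frame.positions[node][1],
                        "colour": frame.colours[node],
                        "r": frame.radii[node],
                        "absent": node in frame.absent,
                    }
                    for node in frame.nodes
                ],
                "edges": [
                    [source, target] for source, target in sorted(frame.edges)
                ],
            }
        )
    return json.dumps(payload)


def _html_page(anim: Animation) -> str:
    return f"""<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>network animation</title>
<style>
  body {{ font-family: sans-serif; margin: 1em; }}
  svg {{ border: 1px solid #ccc; background: #fff; }}
  #label {{ font-weight: bold; margin: 0 1em; }}
</style></head>
<body>
<div>
  <button id="back">&#9664; back</button>
  <span id="label"></span>
  <button id="fwd">forward &#9654;</button>
</div>
<svg id="view" width="640" height="640" viewBox="-0.08 -0.08 1.16 1.16"></svg>
<script>
const frames = {_frame_json(anim)};
let cursor = 0;
const svg = document.getElementById("view");
const NS = "http://www.w3.org/2000/svg";
function show(i) {{
  cursor = Math.max(0, Math.min(frames.length - 1, i));
  const f = frames[cursor];
  document.getElementById("label").textContent =
    f.label + " (" + (cursor + 1) + "/" + frames.length + ")";
  svg.replaceChildren();
  const pos = {{}};
  for (const n of f.nodes) pos[n.id] = n;
  for (const [s, t] of f.edges) {{
    if (!(s in pos) || !(t in pos)) continue;
    const line = document.createElementNS(NS, "line");
    line.setAttribute("x1", pos[s].x); line.setAttribute("y1", 1 - pos[s].y);
    line.setAttribute("x2", pos[t].x); line.setAttribute("y2", 1 - pos[t].y);
    line.setAttribute("stroke", "#999"); line.setAttribute("stroke-width", "0.003");
    svg.appendChild(line);
  }}
  for (const n of f.nodes) {{
    const c = document.createElementNS(NS, "circle");
    c.setAttribute("cx", n.x); c.setAttribute("cy", 1 - n.y);
    c.setAttribute("r", n.r / 640);
    c.setAttribute("fill", n.colour);
    c.setAttribute("opacity", n.absent ? 0.35 : 1.0);
    c.setAttribute("stroke", "#000"); c.setAttribute("stroke-width", "0.001");
    const title = document.createElementNS(NS, "title");
    title.textContent = n.id;
    c.appendChild(title);
    svg.appendChild(c);
  }}
}}
document.getElementById("fwd").addEventListener("click", () => show(cursor + 1));
document.getElementById("back").addEventListener("click", () => show(cursor - 1));
show(0);
</script>
</body>
</html>
"""


# ----------------------------------------------------------------------
# 2D line graph
# ----------------------------------------------------------------------
def line_graph(
    expr: ExpressionSeries,
    node_ids: list[str],
    path: str | Path,
) -> tuple[Path, Path]:
    """Plot expression trajectories for selected nodes over ordered frames.

    One line per node, x axis = frame labels (e.g. ``T8_D1000`` for a
    dose-over-time design), legend = node ids.  Unknown ids are warned
    about and skipped; having none left is an error.  The underlying tidy
    table (node, frame, value) is written next to the plot.
    """
    path = Path(path)
    known = [n for n in node_ids if n in expr.table.index]
    unknown = [n for n in node_ids if n not in expr.table.index]
    if unknown:
        logger.warning("line_graph: skipping unknown node id(s): %s", unknown)
    if not known:
        raise ValueError(f"none of the requested nodes are in the series: {node_ids}")

    frames = expr.frames
    x = np.arange(len(frames))
    fig, ax = plt.subplots(figsize=(6, 4))
    try:
        for node in known:
            ax.plot(x, expr.table.loc[node].to_numpy(dtype=float),
                    marker="o", label=node)
        ax.set_xticks(x)
        ax.set_xticklabels(frames, rotation=45, ha="right")
        ax.set_xlabel("frame")
        ax.set_ylabel("expression")
        ax.axhline(0.0, color="0.8", linewidth=0.8)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path)
    finally:
        plt.close(fig)

    table_path = path.with_suffix(".tsv")
    tidy = expr.to_tidy()
    tidy[tidy["node"].isin(known)].to_csv(
        table_path, sep="\t", index=False, lineterminator="\n"
    )
    return path, table_path
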