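"""Animation assembly, stepping, exports, line graphs."""

import pandas as pd
import pytest
from PIL import Image

from netdyn import (
    ExpressionSeries,
    SizeRule,
    TemporalNetwork,
    build_animation,
    build_colour_scale,
    export_animation,
    export_svg,
    line_graph,
    read_expression,
    step,
    value_to_colour,
    colour_to_hex,
)
from netdyn.animation import UNIFORM_NODE_COLOUR


@pytest.fixture
def static_plus_expr(small_expr):
    net = TemporalNetwork.from_edges(
        [("TLR4", "CXCL2"), ("CCL4", "TLR4")]
    )
    return net, small_expr


def test_node_animation_mode(static_plus_expr):
    """Static network + 3-frame expression: constant edges, changing colours."""
    net, expr = static_plus_expr
    anim = build_animation(net, expr, seed=1)
    assert len(anim) == 3
    assert anim.labels == expr.frames
    edge_sets = {frozenset(f.edges) for f in anim.frames}
    assert len(edge_sets) == 1
    tlr4 = [f.colours["TLR4"] for f in anim.frames]
    assert len(set(tlr4)) == 3  # three distinct values -> three colours


def test_edge_animation_mode(two_frame_net):
    """Dynamic edges, no expression: changing edges, uniform node colour."""
    anim = build_animation(two_frame_net, seed=1)
    assert len(anim) == 2
    assert anim.frames[0].edges != anim.frames[1].edges
    for frame in anim.frames:
        assert set(frame.colours.values()) == {UNIFORM_NODE_COLOUR}


def test_planted_downregulation_turns_node_redder():
    net = TemporalNetwork.from_edges([("g1", "g2")])
    expr = ExpressionSeries.from_dict(
        {"g1": [0.5, -2.0], "g2": [0.1, 0.1]}, frames=["f1", "f2"]
    )
    anim = build_animation(net, expr, seed=0)
    scale = build_colour_scale(expr)
    def red(hexcol):
        return int(hexcol[1:3], 16)
    assert red(anim.frames[1].colours["g1"]) > red(anim.frames[0].colours["g1"])
    # colour consistency with the global scale
    assert anim.frames[1].colours["g1"] == colour_to_hex(
        value_to_colour(scale, -2.0)
    )


def test_same_value_same_colour_across_frames():
    net = TemporalNetwork.from_edges([("a", "b")])
    expr = ExpressionSeries.from_dict(
        {"a": [1.0, 1.0, 1.0], "b": [-3.0, 0.0, 3.0]}, frames=["f1", "f2", "f3"]
    )
    anim = build_animation(net, expr, seed=0)
    assert len({f.colours["a"] for f in anim.frames}) == 1


def test_positions_fixed_across_frames(two_frame_net):
    anim = build_animation(two_frame_net, seed=2)
    p0, p1 = anim.frames[0].positions, anim.frames[1].positions
    assert p0.coords == p1.coords


def test_irreconcilable_frame_labels_error_lists_both(small_expr):
    net = TemporalNetwork.from_frame_edges(
        {"x1": [("TLR4", "CXCL2")], "x2": [("TLR4", "CCL4")]}
    )
    with pytest.raises(ValueError) as excinfo:
        build_animation(net, small_expr)
    message = str(excinfo.value)
    assert "x1" in message and "T2" in message


def test_frame_map_reconciles_labels(small_expr):
    net = TemporalNetwork.from_frame_edges(
        {"early": [("TLR4", "CXCL2")], "late": [("TLR4", "CCL4")]}
    )
    anim = build_animation(
        net, small_expr, frame_map={"early": "T2", "late": "T24"}
    )
    assert len(anim) == 2


def test_degree_based_radii_follow_frame_degrees(two_frame_net):
    anim = build_animation(
        two_frame_net, size_rule=SizeRule(mode="by_total"), seed=0
    )
    for frame in anim.frames:
        degrees = frame.degrees["total"]
        radii = frame.radii
        # larger degree never gets a smaller radius
        for a in radii:
            for b in radii:
                if degrees[a] > degrees[b]:
                    assert radii[a] >= radii[b]


def test_absent_nodes_greyed_or_dropped():
    net = TemporalNetwork.from_frame_edges(
        {"f1": [("A", "B"), ("C", "D")], "f2": [("A", "B")]}
    )
    kept = build_animation(net, seed=0)
    assert kept.frames[1].absent == {"C", "D"}
    assert set(kept.frames[1].nodes) == {"A", "B", "C", "D"}
    dropped = build_animation(net, drop_absent=True, seed=0)
    assert set(dropped.frames[1].nodes) == {"A", "B"}


# ----------------------------------------------------------------------
# stepping
# ----------------------------------------------------------------------
def test_step_clamps_at_both_ends(two_frame_net):
    anim = build_animation(two_frame_net, seed=0)
    assert step(anim, "backward").label == anim.labels[0]  # clamp at start
    step(anim, "forward")
    assert step(anim, "forward").label == anim.labels[-1]  # clamp at end
    assert anim.cursor == 1


def test_step_forward_then_backward_is_identity(two_frame_net):
    anim = build_animation(two_frame_net, seed=0)
    start = anim.current.label
    step(anim, "forward")
    assert step(anim, "backward").label == start


# ----------------------------------------------------------------------
# exports
# ----------------------------------------------------------------------
@pytest.fixture
def three_frame_anim():
    net = TemporalNetwork.from_frame_edges(
        {"f1": [("A", "B")], "f2": [("A", "B"), ("B", "C")], "f3": [("B", "C")]}
    )
    return build_animation(net, seed=0)


def test_gif_preserves_frame_count(three_frame_anim, tmp_path):
    (path,) = export_animation(three_frame_anim, tmp_path / "anim.gif", "gif")
    with Image.open(path) as image:
        assert image.n_frames == 3


def test_png_sequence_naming(three_frame_anim, tmp_path):
    written = export_animation(three_frame_anim, tmp_path / "frames", "png_sequence")
    assert [p.name for p in written] == [
        "frame_001.png",
        "frame_002.png",
        "frame_003.png",
    ]
    assert all(p.exists() for p in written)


def test_html_export_is_self_contained_with_controls(three_frame_anim, tmp_path):
    (path,) = export_animation(three_frame_anim, tmp_path / "anim.html", "html")
    text = path.read_text(encoding="utf-8")
    assert text.count('"label": "f') == 3 or text.count('"label":"f') == 3
    assert 'id="fwd"' in text and 'id="back"' in text
    assert "show(0)" in text  # opens on the first frame
    assert "http" not in text.split("http://www.w3.org")[0]  # no external fetches


def test_svg_single_frame(three_frame_anim, tmp_path):
    path = export_svg(three_frame_anim.frames[0], tmp_path / "frame.svg")
    assert path.read_text(encoding="utf-8").lstrip().startswith("<?xml")


# ----------------------------------------------------------------------
# line graph
# ----------------------------------------------------------------------
def test_line_graph_emits_plot_and_tidy_table(small_expr, tmp_path):
    plot, table = line_graph(
        small_expr, ["TLR4", "CXCL2", "CCL4"], tmp_path / "lines.png"
    )
    assert plot.exists()
    tidy = pd.read_csv(table, sep="\t")
    assert set(tidy.columns) == {"node", "frame", "value"}
    assert len(tidy) == 9
    # data conservation: tidy values round-trip to the input exactly
    for row in tidy.itertuples():
        assert small_expr.value(row.node, row.frame) == pytest.approx(row.value)


def test_line_graph_single_node(small_expr, tmp_path):
    plot, table = line_graph(small_expr, ["TLR4"], tmp_path / "one.png")
    tidy = pd.read_csv(table, sep="\t")
    assert tidy["node"].unique().tolist() == ["TLR4"]


def test_line_graph_skips_unknown_and_errors_when_none_left(small_expr, tmp_path):
    plot, table = line_graph(small_expr, ["TLR4", "NOPE"], tmp_path / "p.png")
    tidy = pd.read_csv(table, sep="\t")
    assert "NOPE" not in set(tidy["node"])
    with pytest.raises(ValueError):
        line_graph(small_expr, ["NOPE"], tmp_path / "q.png")
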