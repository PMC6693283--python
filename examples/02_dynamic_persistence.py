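"""Track edge rewiring over an exposure series and count persistent edges.

A dynamic edge file assigns each interaction to a frame (here: three
exposure days and a washout).  The script reports how a focal node's
neighbourhood grows during exposure and how many of its interactions
survive the washout — the analysis used to separate treatment-driven
interactions (they disappear) from persistent ones.
"""

import tempfile
from pathlib import Path

from netdyn import (
    degree_over_time,
    first_degree_neighbourhood,
    persistence_summary,
    read_dynamic_edges,
)

ROWS = []
PARTNERS = [f"g{i}" for i in range(1, 8)]
# FOCUS gains partners day by day, then keeps only the first four
for day, count in (("day1", 2), ("day2", 5), ("day3", 7), ("washout", 4)):
    for partner in PARTNERS[:count]:
        ROWS.append(f"{partner}\tFOCUS\t{day}")
ROWS += ["g1\tg2\tday2", "g1\tg2\tday3", "g5\tg6\twashout"]

with tempfile.TemporaryDirectory() as workdir:
    path = Path(workdir) / "dynamic_edges.tsv"
    path.write_text("\n".join(ROWS) + "\n", encoding="utf-8")

    net = read_dynamic_edges(path)
    print(f"frames (first-appearance order): {net.frames}\n")

    tidy = degree_over_time(net)
    focus = tidy[tidy.node == "FOCUS"]
    print("degree of FOCUS over time:")
    print(focus.to_string(index=False))

    summary = persistence_summary(net, "day3", "washout")
    print(
        f"\nday3 -> washout: {summary['persistent']} of {summary['edges_a']} "
        f"edges persist, {summary['lost']} are lost, {summary['gained']} appear."
    )
    print("Lost edges are candidates for treatment-driven interactions.")

    sub = first_degree_neighbourhood(net, "FOCUS", "day3")
    print(
        f"\nFOCUS neighbourhood on day3: {len(sub.nodes) - 1} neighbours, "
        f"{len(sub.edge_set())} edges among them."
    )
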