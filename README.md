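# netdyn

**Dynamic (dose-over-time) perturbation analysis and animation on
biological networks.**

High-throughput time-series and dose-response experiments produce
networks that *change*: gene expression shifts frame by frame, and
gene–gene interactions appear and disappear over an exposure and its
washout.  `netdyn` is a headless engine for studying exactly that. It is
aimed at toxicogenomics and systems-biology analysts who have a
regulatory or interaction network plus per-frame measurements and want
to ask: which nodes become hubs, when? which interactions are
treatment-driven and which persist? what does the perturbation look
like, frame by frame?

## What it computes

* **Temporal network model.** A fixed node set with one edge set per
  *frame* (a time point, a dose, or a dose-over-time combination such as
  `T8_D5000`).  Static networks are the one-frame special case. Files
  are auto-detected among two-column edge lists, 0/1 adjacency matrices,
  Cytoscape SIF, and long-format dynamic edge lists.

* **Degree decomposition.** Directed degree centrality split per frame
  into *inner* degree `k_in(v) = |{u : u → v}|` (the node is regulated),
  *outer* degree `k_out(v) = |{u : v → u}|` (the node regulates) and
  total `k(v) = k_in(v) + k_out(v)`; plus degree-threshold filtering,
  first-degree neighbourhoods, and persistent-edge counts
  `|E(f_a) ∩ E(f_b)|` between any two frames.

* **Deterministic layout.** A Fruchterman–Reingold spring embedding
  (attraction `d²/k` along edges, repulsion `k²/d` between all pairs)
  normalized to the unit square, with a closed-form 3D lift

  `z = 0.8·y·sin(πy) + 0.8·x·sin(πx)`,  x, y ∈ [0, 1].

* **Symmetric colour scale.** Expression maps linearly onto a
  red↔green (or red↔blue) diverging ramp over `[-M, +M]` with
  `M = max |x|` over the *whole* series, so a full red means exactly as
  much downregulation as a full green means upregulation, in every frame.

* **Animation.** One resolved frame per condition (positions, colours,
  radii, active edges, degrees), steppable forward/backward, exportable
  as animated GIF, numbered PNG sequence, single-frame SVG, or a
  self-contained HTML page; plus 2D line graphs of selected nodes'
  trajectories with their tidy data table.

* **Local annotation.** Gene info / pathway / disease lookups from three
  flat TSV tables per species, and pathway ranking by the number of
  distinct network genes (top 10 returned, full list exportable).

* **Synthetic study generator.** A seeded generator that plants a focal
  hub with an exposure-growth/washout-persistence schedule and known
  expression trajectories, writing files in the exact dialects the
  parsers read together with a ground-truth JSON — the basis of the
  end-to-end tests.

## Worked example

```python
from netdyn import (TemporalNetwork, ExpressionSeries, build_colour_scale,
                    build_animation, degree_over_time)

net = TemporalNetwork.from_frame_edges({
    "day1": [("g1", "FOCUS"), ("g2", "FOCUS")],
    "day2": [("g1", "FOCUS"), ("g2", "FOCUS"), ("g3", "FOCUS"), ("FOCUS", "g4")],
    "washout": [("g1", "FOCUS"), ("FOCUS", "g4")],
})
print(degree_over_time(net)[lambda t: t.node == "FOCUS"])
```

```
     node    frame  inner  outer  total
1   FOCUS     day1      2      0      2
6   FOCUS     day2      3      1      4
11  FOCUS  washout      1      1      2
```

FOCUS gains interactions during exposure (total degree 2 → 4) and keeps
two of them after washout; `persistent_edges(net, "day2", "washout")`
returns exactly those two.  The `examples/` directory holds one short
script per capability (parsing and degrees, persistence, 3D layout,
colours and animation export, pathway ranking, simulate-and-recover);
each prints the numbers it computes and what they mean.

A thin CLI mirrors the library:

```bash
netdyn simulate --seed 7 --out sim/
netdyn degrees --dynamic-edges sim/dynamic_edges.tsv --out deg/
netdyn animate --dynamic-edges sim/dynamic_edges.tsv \
               --expression sim/expression.tsv --format gif --out anim/
```

Every run writes a `run_metadata.json` (inputs, options, seed, version)
so its artefacts are reproducible from the output directory alone.

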