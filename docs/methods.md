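# Methods

## The temporal network model

A study is modelled as a node set `V` plus an ordered list of frames
`f_1 … f_T`, each with its own edge set `E(f_t) ⊆ V × V`.  A frame is
whatever one experimental condition is: a time point, a dose, or a
dose-over-time combination.  A static network is the degenerate case
`T = 1`; when a static topology is animated against a multi-frame
expression series it is replicated over the expression frames (the
topology is constant, only colours change).

Edges are identified by their ordered `(source, target)` pair.  An
optional relation token (from SIF files) is carried along but never
participates in edge identity — in particular, persistence between two
frames is `E(f_a) ∩ E(f_b)` on pairs alone.  For undirected networks the
pair is stored in sorted order so `(A,B)` and `(B,A)` coincide.
Duplicate edges within a frame collapse; self-loops are kept.

Assumptions: node identifiers are case-sensitive, whitespace-trimmed
strings with no normalization (identifier mapping is the annotation
store's concern); directedness is a global per-network flag, defaulting
to directed because the motivating networks are regulatory ("A regulates
B" has a direction).

## Format detection

Files are tokenized by trying tab, comma, semicolon, then any
whitespace, taking the first delimiter that gives consistent column
counts (an adjacency header one token shorter than its body — the empty
corner cell — is tolerated).  Classification is deterministic and
total:

1. a square grid with row+column labels whose body cells are all 0/1 is
   an **adjacency matrix**;
2. uniformly two-column rows are an **edge list**;
3. three or more columns are either **SIF** (middle column = small
   relation vocabulary) or a **dynamic edge list** (third column = small
   frame-label vocabulary).  A `.sif` extension, a configured
   frame-label set, or a header naming the third column
   (frame/time/dose/day/…) decides directly; otherwise whichever column
   has the small repeating vocabulary (at most half the row count)
   decides, and a tie is **UNKNOWN** — never a silent guess.

A two-column edge list whose node names happen to be `0`/`1` in a
labelled square arrangement is indistinguishable from an adjacency
matrix; the committed rule prefers the adjacency reading.  Practical
gene networks never hit this corner.

## Degree conventions

`inner(v)` counts edges into `v`, `outer(v)` edges out of `v`,
`total = inner + outer`.  A self-loop adds 1 to inner *and* 1 to outer
(so 2 to total) — the consistent choice that keeps the handshake
identity `Σ inner = Σ outer = |E|` exact.  For undirected networks the
in/out split is not meaningful and all three components equal the
incident edge count, with a self-loop counted once.  Degrees are always
per frame; the only cross-frame product is the exported tidy table
(node, frame, inner, outer, total).  Per-frame computation is delegated
to networkx in/out-degree; the test suite checks it against an
independent naive edge-scan oracle on random digraphs.

Threshold filtering retains nodes whose chosen degree component is at
least the threshold, plus edges whose both endpoints survive; it is
monotone in the threshold.  The first-degree neighbourhood of `v` is
`{v}` plus all in- and out-neighbours in the frame, with *all* frame
edges among that set (including neighbour–neighbour edges), which is
the view used to inspect a gene whose expression changes sharply.

## Layout

2D positions come from a Fruchterman–Reingold spring model: attraction
`d²/k` along each edge, repulsion `k²/d` between every pair, per-sweep
displacement capped by a temperature starting at 0.1 and cooling by
×0.97, 300 sweeps by default.  `k` (natural spring length) defaults to
`sqrt(1/n)`, the area-equipartition heuristic.  The constants are
anchored by a closed form: for two connected nodes the forces balance
exactly at distance `k`, and a long run converges there (tested to
0.1 % relative error).  Initial positions are drawn for nodes in sorted
order from a seeded generator, making the layout deterministic and
independent of node input order.  Self-loops exert no force; a single
node sits at (0.5, 0.5) by convention.

Final coordinates are min–max normalized to [0, 1] per axis (a
degenerate axis maps to 0.5).  The 3D lift is applied *after*
normalization — the formula is only defined on the unit square and the
implementation rejects non-normalized input:

    z = 0.8 · y · sin(πy) + 0.8 · x · sin(πx)

so `z = 0` whenever both coordinates lie on the square's boundary
values {0, 1}, `z = 0.8` at the centre, and `|z| ≤ 0.8(x+y) ≤ 1.6`
everywhere (since `|sin| ≤ 1`).

During animation, positions are computed once on the union of all
frames' edges and held fixed, so frames differ only in colours, radii
and active edges and remain visually comparable.  Per-frame relayout is
available by laying out each frame explicitly, but it is not the
default: moving nodes between frames confounds expression changes with
position changes.

## Colour and size mapping

The colour domain is `[-M, +M]` with `M = max |x|` over the entire
series — all nodes, all frames jointly — so the same value gets the
same colour in every frame and the two directions of regulation are
visually symmetric.  The ramp is linear per RGB channel through a
near-black neutral at 0: full red (255,0,0) at `-M`, (0,0,0) at 0, full
green (0,255,0) (or blue) at `+M`.  Channel interpolation rounds half
up, so `v = M/2` gives channel 128 exactly.  Values outside the domain
clamp (this can only happen when a scale is reused on different data);
missing values render mid-grey (128,128,128), deliberately distinct
from the zero colour because "not measured" is not "unchanged".  An
all-zero series yields the degenerate domain [0,0] and everything
neutral.

Node radius maps the chosen degree component linearly from
`[0, max observed degree]` onto `[min_radius, max_radius]` (defaults
6–24 display units); fixed mode is a constant.  The observed maximum is
taken over all frames so sizes, like colours, are comparable across the
animation.

## Annotation and ranking

The annotation store is three flat TSV tables per species (gene info
with Entrez id, symbol, `|`-separated synonyms and gene type;
gene→pathway; gene→disease).  Malformed rows are skipped with a logged
count; duplicate associations collapse; lookups are total — an unknown
gene yields an empty record flagged unannotated, never an error.
Pathway ranking counts **distinct genes**, not associations: duplicate
query ids count once, each pathway's count is the size of its member
set, ordering is count-descending with alphabetical tie-break, and the
top-10 table is by construction a prefix of the exportable full list.

## Animation and exports

An animation frame bundles label, positions, hex colours, radii, the
frame's active edge set and its degree table.  Stepping clamps at both
ends (stepping forward past the last frame stays on the last frame).
Edge transitions are hard cuts — an edge is present or absent per
frame, no tweening — matching the discrete-frame nature of the data.
Nodes with no incident edge in a frame stay drawn at 35 % opacity so
the layout reads consistently; `drop_absent` removes them instead.
GIF frame duration defaults to 1000 ms.  The HTML export embeds the
frame JSON and ~40 lines of stepping script; it is a static artefact
with no external requests.  The line graph plots one line per selected
node over the ordered frame labels and writes the underlying tidy
(node, frame, value) table next to it.

## The synthetic generator

`FixtureSpec` emulates an exposure/washout interaction study plus a
dose-over-time expression study on the same frames:

* **Focal hub.** Exact in/out spoke counts per frame, drawn by prefix
  from fixed shuffled partner pools (in- and out-pools disjoint).  The
  prefix rule makes the planted persistence explicit: a frame keeps
  exactly the first `min(k_t, k_{t+1})` partners of the previous frame.
  The default schedule — 10 interactions (7 in / 3 out) on day 1,
  growing to 71 (49/22) by day 3, with 50 (35/15) kept after washout —
  reproduces the interaction-growth-then-partial-persistence shape of a
  hepatocyte drug-exposure study with a 3-day washout.  The hub takes no
  background edges, so its planted degrees are its exact degrees.
* **Background turnover.** Ordered non-hub pairs start present with
  probability 0.02 and then die at 0.25 / are born at 0.01 per frame —
  sparse, with substantial rewiring between frames, as in
  interaction networks assembled per time point.
* **Expression.** Planted trajectories (default: the hub dips to −3.2
  at peak exposure and rebounds) on top of N(0, 0.5) noise for other
  genes, rounded to 4 decimals for clean text round-trips.
* **Annotations.** Every gene gets an info row, 1–3 pathways from a
  15-pathway pool and a 30 % chance of one disease from a 7-disease
  pool — enough structure to exercise ranking, tie-breaks and the
  top-10 cut.

What the generator does **not** emulate: correlated expression between
interacting genes, degree-distribution realism (background is
Erdős–Rényi-like), measurement-platform artefacts, or identifier messiness.
Passing the recovery tests therefore demonstrates that the pipeline
preserves and reports the planted structure exactly — not that the
method would denoise or infer anything from real data (it performs no
inference; it is an analysis and visualization engine).

All sizes are desk-scale by choice: 100 nodes × 4 frames generates in
well under a second and keeps the whole suite fast while still being an
order of magnitude larger than the worked examples.

## Numerical and degenerate-input choices

* Delimiter sniffing order: tab, comma, semicolon, whitespace — first
  consistent wins; a file with no multi-token interpretation is a parse
  error naming the first offending line.
* Expression cells that are empty, `NA` or `NaN` are missing, not zero.
* Layout epsilon 1e-9 guards zero distances; coincident initial points
  cannot occur with a continuous RNG but a degenerate axis after
  convergence maps to 0.5.
* Ranking of an unannotated query is empty, not an error; a query list
  itself must be non-empty.
* Writing a multi-frame network to a static format requires an explicit
  frame selection; text edge formats cannot carry isolated nodes, which
  is the one caveat on round-trip identity.

## Known limitations

* No interactive rendering: 3D coordinates and HTML frames are exported
  as data/static artefacts; there is no drag-and-drop or fly-through.
* No weighted edges, no centralities beyond degree, no enrichment
  statistics (ranking is by raw count, deliberately).
* Annotation tables must be prepared offline; the package does not
  query pathway or disease databases.
* The SIF/dynamic-edge disambiguation is heuristic where no extension,
  header or configuration hint exists; ambiguous three-column files
  should be read with an explicit format.
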