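"""Synthetic temporal-network fixture generator.

Emulates the structure of the two kinds of experiment the engine is
built for, at desk scale:

* an *edge-rewiring* experiment: a focal hub gene whose interaction
  count grows over an exposure period and partially persists after a
  washout, on top of a background of edges that are born and die at
  fixed per-frame probabilities (the dynamics seen in time-resolved
  gene-gene interaction networks after drug exposure);
* a *node-expression* experiment: planted per-gene expression
  trajectories (e.g. a sharp downregulation at one frame) over the same
  ordered frames, with unplanted genes drawing small Gaussian noise.

Everything is reproducible from one seed, and the planted structure is
recorded in a ground-truth JSON so that analysis results can be checked
against construction rather than against the analysis itself.

Defaults mirror a 3-day exposure plus washout design: the hub starts
with 10 neighbours (7 regulating it, 3 regulated by it), grows to 71
interactions (49 in, 22 out) by the last exposure frame, and keeps 50
of those 71 (35 in, 15 out) after washout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationStore
from .model import ExpressionSeries, TemporalNetwork
from .io import write_expression, write_network, NetworkFormat

__all__ = [
    "HubSpec",
    "FixtureSpec",
    "Fixture",
    "scaled_hub",
    "build_fixture",
    "generate_fixture",
]

PATHWAY_POOL = (
    "Apoptosis",
    "Cell cycle",
    "Chemokine signaling",
    "DNA damage response",
    "Drug metabolism - cytochrome P450",
    "ECM-receptor interaction",
    "Fatty acid metabolism",
    "Focal adhesion",
    "Inflammatory response",
    "NF-kB signaling",
    "Oxidative stress response",
    "TNF signaling",
    "Toll-like receptor signaling",
    "Wnt signaling",
    "p53 signaling",
)

DISEASE_POOL = (
    "Chemical and Drug Induced Liver Injury",
    "Cholestasis",
    "Drug-Induced Liver Injury",
    "Fibrosis",
    "Hepatomegaly",
    "Liver Cirrhosis",
    "Neoplasms",
)


@dataclass(frozen=True)
class HubSpec:
    """Planted focal node: exact in/out spoke counts per frame.

    Spokes are drawn from a fixed shuffled partner pool by prefix, so a
    frame with fewer spokes than the one before keeps a subset of its
    edges — that intersection is the planted persistent set.
    """

    node: str = "HUB"
    inner_per_frame: tuple[int, ...] = (7, 28, 49, 35)
    outer_per_frame: tuple[int, ...] = (3, 12, 22, 15)

    @property
    def total_per_frame(self) -> tuple[int, ...]:
        return tuple(
            i + o for i, o in zip(self.inner_per_frame, self.outer_per_frame)
        )


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for one synthetic data set."""

    n_nodes: int = 100
    frame_labels: tuple[str, ...] = ("day1", "day2", "day3", "washout")
    edge_p: float = 0.02  # background edge density in the first frame
    birth_p: float = 0.01  # per-frame birth probability of an absent pair
    death_p: float = 0.25  # per-frame death probability of a present edge
    hub: HubSpec = field(default_factory=HubSpec)
    trajectories: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"HUB": (-0.3, -1.6, -3.2, -0.9)}
    )
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.edge_p, self.birth_p, self.death_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        n_frames = len(self.frame_labels)
        if len(self.hub.inner_per_frame) != n_frames:
            raise ValueError("hub inner_per_frame length must match frame count")
        if len(self.hub.outer_per_frame) != n_frames:
            raise ValueError("hub outer_per_frame length must match frame count")
        # in- and out-partner pools are disjoint, so both maxima must fit
        needed = max(self.hub.inner_per_frame) + max(self.hub.outer_per_frame)
        if needed > self.n_nodes - 1:
            raise ValueError(
                f"hub needs {needed} partners but only "
                f"{self.n_nodes - 1} other nodes exist"
            )
        for node, values in self.trajectories.items():
            if len(values) != n_frames:
                raise ValueError(
                    f"trajectory for {node!r} has {len(values)} values, "
                    f"expected {n_frames}"
                )


def scaled_hub(n_nodes: int, base: HubSpec | None = None) -> HubSpec:
    """Shrink a hub schedule proportionally so it fits ``n_nodes``.

    Keeps the grow-then-washout shape while capping the combined in/out
    partner demand at ``n_nodes - 1``; used when generating small data
    sets from the default schedule.
    """
    base = base or HubSpec()
    cap = n_nodes - 1
    needed = max(base.inner_per_frame) + max(base.outer_per_frame)
    if needed <= cap:
        return base
    factor = cap / needed
    return HubSpec(
        node=base.node,
        inner_per_frame=tuple(max(1, int(v * factor)) for v in base.inner_per_frame),
        outer_per_frame=tuple(max(1, int(v * factor)) for v in base.outer_per_frame),
    )


@dataclass
class Fixture:
    """In-memory synthetic data set plus its planted ground truth."""

    spec: FixtureSpec
    network: TemporalNetwork
    expression: ExpressionSeries
    annotations: AnnotationStore
    ground_truth: dict


def _node_names(n: int, hub_name: str) -> list[str]:
    names = [hub_name]
    names += [f"G{i:03d}" for i in range(1, n)]
    return names


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the data set in memory."""
    rng = np.random.default_rng(spec.seed)
    frames = list(spec.frame_labels)
    nodes = _node_names(spec.n_nodes, spec.hub.node)
    others = nodes[1:]

    # --- hub spokes: disjoint in/out partner pools, prefix-nested ------
    shuffled = list(rng.permutation(others))
    max_in = max(spec.hub.inner_per_frame)
    in_pool = shuffled[:max_in]
    out_pool = shuffled[max_in : max_in + max(spec.hub.outer_per_frame)]

    hub_edges: dict[str, set[tuple[str, str]]] = {}
    for frame, n_in, n_out in zip(
        frames, spec.hub.inner_per_frame, spec.hub.outer_per_frame
    ):
        inward = {(str(p), spec.hub.node) for p in in_pool[:n_in]}
        outward = {(spec.hub.node, str(p)) for p in out_pool[:n_out]}
        hub_edges[frame] = inward | outward

    # --- background edges among non-hub nodes: birth/death chain ------
    pairs = [(u, v) for u in others for v in others if u != v]
    present = np.asarray(rng.random(len(pairs)) < spec.edge_p)
    background: dict[str, set[tuple[str, str]]] = {}
    for index, frame in enumerate(frames):
        if index > 0:
            dies = rng.random(len(pairs)) < spec.death_p
            born = rng.random(len(pairs)) < spec.birth_p
            present = (present & ~dies) | (~present & born)
        background[frame] = {
            pair for pair, on in zip(pairs, present) if on
        }

    frame_edges = {f: hub_edges[f] | background[f] for f in frames}
    network = TemporalNetwork.from_frame_edges(
        {f: sorted(frame_edges[f]) for f in frames},
        directed=True,
        frame_order=frames,
    )
    # keep every node present even when isolated in all frames
    missing = [v for v in nodes if v not in network.nodes]
    network = TemporalNetwork(
        network.nodes + missing,
        network.frames,
        network.edges_by_frame,
        directed=True,
    )

    # --- expression: planted trajectories + Gaussian background -------
    values = {}
    for node in nodes:
        if node in spec.trajectories:
            values[node] = [round(v, 4) for v in spec.trajectories[node]]
        else:
            values[node] = [
                round(float(v), 4)
                for v in rng.normal(0.0, spec.noise_sd, size=len(frames))
            ]
    expression = ExpressionSeries(
        pd.DataFrame.from_dict(values, orient="index", columns=frames)
    )

    # --- mini annotation tables ----------------------------------------
    store = AnnotationStore(species="Homo sapiens")
    for index, node in enumerate(nodes):
        store.gene_info[node] = {
            "symbol": node,
            "entrez_id": str(1000 + index),
            "synonyms": (f"{node}-A", f"{node}-B"),
            "gene_type": "protein-coding",
        }
        n_pathways = int(rng.integers(1, 4))
        picks = rng.choice(len(PATHWAY_POOL), size=n_pathways, replace=False)
        store.gene_pathways[node] = {PATHWAY_POOL[i] for i in picks}
        if rng.random() < 0.3:
            store.gene_diseases[node] = {
                DISEASE_POOL[int(rng.integers(0, len(DISEASE_POOL)))]
            }

    # --- planted ground truth -----------------------------------------
    hub_persistent = {
        f"{a}->{b}": sorted(
            "\t".join(e) for e in hub_edges[a] & hub_edges[b]
        )
        for a, b in zip(frames, frames[1:])
    }
    ground_truth = {
        "seed": spec.seed,
        "frames": frames,
        "hub": {
            "node": spec.hub.node,
            "inner": list(spec.hub.inner_per_frame),
            "outer": list(spec.hub.outer_per_frame),
            "total": list(spec.hub.total_per_frame),
        },
        "hub_persistent_counts": {
            key: len(edges) for key, edges in hub_persistent.items()
        },
        "frame_edge_counts": {f: len(frame_edges[f]) for f in frames},
        "frame_persistent_counts": {
            f"{a}->{b}": len(frame_edges[a] & frame_edges[b])
            for a, b in zip(frames, frames[1:])
        },
        "trajectories": {
            node: [round(v, 4) for v in vals]
            for node, vals in spec.trajectories.items()
        },
        "max_abs_expression": float(
            max(abs(v) for row in values.values() for v in row)
        ),
    }
    return Fixture(spec, network, expression, store, ground_truth)


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate the data set and write it in the dialects the readers parse.

    Writes (all UTF-8, Unix newlines, deterministic given the seed):
    ``network.tsv`` (first frame as a static edge list),
    ``dynamic_edges.tsv``, ``expression.tsv``, the three annotation
    tables under ``annotations/``, and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = build_fixture(spec)

    paths = {
        "network": outdir / "network.tsv",
        "dynamic_edges": outdir / "dynamic_edges.tsv",
        "expression": outdir / "expression.tsv",
        "gene_info": outdir / "annotations" / "gene_info.tsv",
        "gene_pathway": outdir / "annotations" / "gene_pathway.tsv",
        "gene_disease": outdir / "annotations" / "gene_disease.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    (outdir / "annotations").mkdir(exist_ok=True)

    write_network(
        fixture.network,
        paths["network"],
        NetworkFormat.EDGE_LIST,
        frame=fixture.network.frames[0],
    )
    write_network(fixture.network, paths["dynamic_edges"], NetworkFormat.DYNAMIC_EDGE_LIST)
    write_expression(fixture.expression, paths["expression"])

    store = fixture.annotations
    info_lines = [
        "\t".join(
            (
                node,
                str(info["entrez_id"]),
                "|".join(info["synonyms"]),  # type: ignore[arg-type]
                str(info["gene_type"]),
            )
        )
        for node, info in sorted(store.gene_info.items())
    ]
    paths["gene_info"].write_text("\n".join(info_lines) + "\n", encoding="utf-8")
    pathway_lines = [
        f"{gene}\t{pathway}"
        for gene in sorted(store.gene_pathways)
        for pathway in sorted(store.gene_pathways[gene])
    ]
    paths["gene_pathway"].write_text("\n".join(pathway_lines) + "\n", encoding="utf-8")
    disease_lines = [
        f"{gene}\t{disease}"
        for gene in sorted(store.gene_diseases)
        for disease in sorted(store.gene_diseases[gene])
    ]
    paths["gene_disease"].write_text(
        ("\n".join(disease_lines) + "\n") if disease_lines else "",
        encoding="utf-8",
    )
    paths["ground_truth"].write_text(
        json.dumps(fixture.ground_truth, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return paths
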