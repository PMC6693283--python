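"""Local biological-knowledge tables: per-gene info and pathway ranking.

The store emulates an integrated annotation database with three flat TSV
tables per species (Homo sapiens, Rattus norvegicus or Mus musculus):

* ``gene_info.tsv``     symbol, entrez id, synonyms (``|``-separated), gene type
* ``gene_pathway.tsv``  symbol, pathway name          (one association per row)
* ``gene_disease.tsv``  symbol, disease name          (one association per row)

Lookups are total: an unknown gene yields an empty, explicitly
unannotated record rather than an error, so annotation never blocks a
purely topological analysis.  Pathway ranking counts *distinct* network
genes per pathway and returns the ten largest (ties broken
alphabetically by pathway name), with the complete list available for
export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SPECIES",
    "GeneRecord",
    "AnnotationStore",
    "PathwayRanking",
    "load_annotations",
    "rank_pathways",
    "write_ranking",
]

logger = logging.getLogger(__name__)

SPECIES = ("Homo sapiens", "Rattus norvegicus", "Mus musculus")

TOP_N = 10


@dataclass(frozen=True)
class GeneRecord:
    """Biological annotation for one node (the pop-up content)."""

    node_id: str
    entrez_id: str | None = None
    symbol: str | None = None
    synonyms: tuple[str, ...] = ()
    gene_type: str | None = None
    pathways: tuple[str, ...] = ()
    diseases: tuple[str, ...] = ()

    @property
    def annotated(self) -> bool:
        return any(
            (
                self.entrez_id,
                self.symbol,
                self.synonyms,
                self.gene_type,
                self.pathways,
                self.diseases,
            )
        )


@dataclass
class AnnotationStore:
    species: str
    gene_info: dict[str, dict[str, object]] = field(default_factory=dict)
    gene_pathways: dict[str, set[str]] = field(default_factory=dict)
    gene_diseases: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"species must be one of {SPECIES}, got {self.species!r}"
            )

    def node_info(self, node_id: str) -> GeneRecord:
        """Annotation record for a node; empty + unannotated when unknown."""
        info = self.gene_info.get(node_id, {})
        return GeneRecord(
            node_id=node_id,
            entrez_id=info.get("entrez_id"),  # type: ignore[arg-type]
            symbol=info.get("symbol"),  # type: ignore[arg-type]
            synonyms=tuple(info.get("synonyms", ())),  # type: ignore[arg-type]
            gene_type=info.get("gene_type"),  # type: ignore[arg-type]
            pathways=tuple(sorted(self.gene_pathways.get(node_id, ()))),
            diseases=tuple(sorted(self.gene_diseases.get(node_id, ()))),
        )

    @property
    def pathways(self) -> set[str]:
        out: set[str] = set()
        for names in self.gene_pathways.values():
            out |= names
        return out


def _read_pairs(path: Path, label: str) -> Iterable[tuple[str, str]]:
    """Yield (key, value) pairs from a two-column TSV, skipping malformed
    rows with a warning summary."""
    skipped = 0
    total = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        total += 1
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            skipped += 1
            continue
        yield fields[0], fields[1]
    if skipped:
        logger.warning(
            "%s: skipped %d of %d malformed row(s) in %s", label, skipped, total, path
        )


def load_annotations(
    species: str,
    gene_info_table: str | Path,
    pathway_table: str | Path,
    disease_table: str | Path,
) -> AnnotationStore:
    """Build an in-memory store from the three flat tables.

    Malformed rows are skipped with a logged count; a missing file is an
    error.  Duplicate (gene, pathway) or (gene, disease) rows collapse.
    """
    store = AnnotationStore(species=species)
    info_path = Path(gene_info_table)
    if not info_path.exists():
        raise FileNotFoundError(info_path)

    skipped = 0
    total = 0
    for line in info_path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        total += 1
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 4 or not fields[0]:
            skipped += 1
            continue
        symbol, entrez, synonyms, gene_type = fields[:4]
        store.gene_info[symbol] = {
            "symbol": symbol,
            "entrez_id": entrez or None,
            "synonyms": tuple(s for s in synonyms.split("|") if s),
            "gene_type": gene_type or None,
        }
    if skipped:
        logger.warning(
            "gene_info: skipped %d of %d malformed row(s) in %s",
            skipped,
            total,
            info_path,
        )

    for table, target, label in (
        (Path(pathway_table), store.gene_pathways, "gene_pathway"),
        (Path(disease_table), store.gene_diseases, "gene_disease"),
    ):
        if not table.exists():
            raise FileNotFoundError(table)
        for gene, name in _read_pairs(table, label):
            target.setdefault(gene, set()).add(name)

    logger.info(
        "annotation store (%s): %d gene records, %d pathway-annotated genes, "
        "%d disease-annotated genes",
        species,
        len(store.gene_info),
        len(store.gene_pathways),
        len(store.gene_diseases),
    )
    return store


@dataclass
class PathwayRanking:
    """Pathways ordered by the number of distinct network genes annotated
    to them (descending), ties alphabetical.  ``top`` is the first
    ``TOP_N`` entries of ``full``; the full list is exportable."""

    full: list[tuple[str, int, tuple[str, ...]]]

    @property
    def top(self) -> list[tuple[str, int, tuple[str, ...]]]:
        return self.full[:TOP_N]


def rank_pathways(store: AnnotationStore, node_ids: Sequence[str]) -> PathwayRanking:
    """Rank pathways by how many distinct query genes they contain.

    Duplicate node ids in the query are counted once.  Genes without
    pathway annotation simply contribute nothing; an entirely
    unannotated query yields an empty ranking.
    """
    if not node_ids:
        raise ValueError("node_ids must be non-empty")
    members: dict[str, set[str]] = {}
    for gene in set(node_ids):
        for pathway in store.gene_pathways.get(gene, ()):
            members.setdefault(pathway, set()).add(gene)
    full = sorted(
        (
            (pathway, len(genes), tuple(sorted(genes)))
            for pathway, genes in members.items()
        ),
        key=lambda item: (-item[1], item[0]),
    )
    return PathwayRanking(full=full)


def write_ranking(
    ranking: PathwayRanking, path: str | Path, *, top_only: bool = False
) -> Path:
    """Export a ranking as TSV: pathway, n_genes, genes (';'-separated)."""
    path = Path(path)
    rows = ranking.top if top_only else ranking.full
    lines = ["pathway\tn_genes\tgenes"]
    for pathway, count, genes in rows:
        lines.append(f"{pathway}\t{count}\t{';'.join(genes)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
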