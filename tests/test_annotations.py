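"""Annotation store loading, node info lookups, pathway ranking."""

import numpy as np
import pytest

from netdyn import AnnotationStore, load_annotations, rank_pathways, write_ranking
from netdyn.annotations import TOP_N


@pytest.fixture
def tables(tmp_path):
    (tmp_path / "gene_info.tsv").write_text(
        "TLR4\t7099\tARMD10|CD284\tprotein-coding\n"
        "CXCL2\t2920\tGRO2|GROb\tprotein-coding\n"
        "bad row without enough fields\n"
        "FN1\t2335\tCIG|ED-B\tprotein-coding\n",
        encoding="utf-8",
    )
    (tmp_path / "gene_pathway.tsv").write_text(
        "TLR4\tToll-like receptor signaling\n"
        "TLR4\tNF-kB signaling\n"
        "CXCL2\tNF-kB signaling\n"
        "CXCL2\tNF-kB signaling\n"  # duplicate association
        "FN1\tFocal adhesion\n",
        encoding="utf-8",
    )
    (tmp_path / "gene_disease.tsv").write_text(
        "TLR4\tLiver Cirrhosis\n", encoding="utf-8"
    )
    return tmp_path


def _load(tmp_path):
    return load_annotations(
        "Homo sapiens",
        tmp_path / "gene_info.tsv",
        tmp_path / "gene_pathway.tsv",
        tmp_path / "gene_disease.tsv",
    )


def test_load_skips_malformed_rows_and_dedupes(tables):
    store = _load(tables)
    assert set(store.gene_info) == {"TLR4", "CXCL2", "FN1"}
    assert store.gene_pathways["CXCL2"] == {"NF-kB signaling"}
    assert store.pathways == {
        "Toll-like receptor signaling",
        "NF-kB signaling",
        "Focal adhesion",
    }


def test_missing_file_errors(tables):
    with pytest.raises(FileNotFoundError):
        load_annotations(
            "Homo sapiens",
            tables / "nope.tsv",
            tables / "gene_pathway.tsv",
            tables / "gene_disease.tsv",
        )


def test_invalid_species_rejected():
    with pytest.raises(ValueError):
        AnnotationStore(species="Danio rerio")


def test_node_info_populated_record(tables):
    record = _load(tables).node_info("TLR4")
    assert record.annotated
    assert record.entrez_id == "7099"
    assert record.synonyms == ("ARMD10", "CD284")
    assert record.gene_type == "protein-coding"
    assert "NF-kB signaling" in record.pathways
    assert record.diseases == ("Liver Cirrhosis",)


def test_node_info_unknown_gene_is_empty_not_error(tables):
    record = _load(tables).node_info("XYZ123")
    assert not record.annotated
    assert record.pathways == () and record.diseases == ()


def test_node_info_pathways_without_diseases(tables):
    record = _load(tables).node_info("CXCL2")
    assert record.pathways == ("NF-kB signaling",)
    assert record.diseases == ()


def test_empty_disease_table_is_valid(tmp_path, tables):
    (tables / "gene_disease.tsv").write_text("", encoding="utf-8")
    store = _load(tables)
    assert store.node_info("TLR4").diseases == ()


# ----------------------------------------------------------------------
# ranking
# ----------------------------------------------------------------------
def test_rank_counts_distinct_genes(tables):
    store = _load(tables)
    ranking = rank_pathways(store, ["TLR4", "CXCL2", "FN1"])
    assert ranking.full[0] == ("NF-kB signaling", 2, ("CXCL2", "TLR4"))
    counts = {name: n for name, n, _ in ranking.full}
    assert counts == {
        "NF-kB signaling": 2,
        "Focal adhesion": 1,
        "Toll-like receptor signaling": 1,
    }


def test_rank_invariant_under_duplicate_query_ids(tables):
    store = _load(tables)
    once = rank_pathways(store, ["TLR4", "CXCL2"])
    doubled = rank_pathways(store, ["TLR4", "TLR4", "CXCL2", "CXCL2"])
    assert once.full == doubled.full


def test_rank_ties_break_alphabetically(tables):
    store = _load(tables)
    ranking = rank_pathways(store, ["TLR4", "FN1"])
    tied = [name for name, n, _ in ranking.full if n == 1]
    assert tied == sorted(tied)


def test_top10_is_prefix_of_full_export():
    store = AnnotationStore(species="Homo sapiens")
    # 15 pathways: gene g_i belongs to P00..P_i, so pathway P_j has 15 - j members
    for i in range(15):
        store.gene_pathways[f"g{i}"] = {f"P{j:02d}" for j in range(i + 1)}
    ranking = rank_pathways(store, [f"g{i}" for i in range(15)])
    assert len(ranking.top) == TOP_N
    assert ranking.full[:TOP_N] == ranking.top
    assert len(ranking.full) >= TOP_N


def test_rank_counts_match_brute_force_oracle():
    rng = np.random.default_rng(13)
    store = AnnotationStore(species="Mus musculus")
    genes = [f"g{i:03d}" for i in range(200)]
    pathways = [f"pathway {i:02d}" for i in range(40)]
    for gene in genes:
        picks = rng.choice(40, size=int(rng.integers(0, 5)), replace=False)
        if picks.size:
            store.gene_pathways[gene] = {pathways[i] for i in picks}
    query = genes[:150]
    ranking = rank_pathways(store, query)
    # naive double loop, independent of the store's ranking path
    expected: dict[str, set[str]] = {}
    for pathway in pathways:
        for gene in set(query):
            if pathway in store.gene_pathways.get(gene, ()):
                expected.setdefault(pathway, set()).add(gene)
    assert {name: n for name, n, _ in ranking.full} == {
        p: len(g) for p, g in expected.items()
    }
    # conservation: summed member counts = number of association pairs
    n_pairs = sum(
        len(store.gene_pathways.get(g, ())) for g in set(query)
    )
    assert sum(n for _, n, _ in ranking.full) == n_pairs
    # ordering: counts descending, ties alphabetical
    keys = [(-n, name) for name, n, _ in ranking.full]
    assert keys == sorted(keys)


def test_ranking_export_roundtrip(tables, tmp_path):
    store = _load(tables)
    ranking = rank_pathways(store, ["TLR4", "CXCL2", "FN1"])
    path = write_ranking(ranking, tmp_path / "ranking.tsv")
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "pathway\tn_genes\tgenes"
    assert lines[1] == "NF-kB signaling\t2\tCXCL2;TLR4"


def test_empty_ranking_for_unannotated_query(tables):
    ranking = rank_pathways(_load(tables), ["UNKNOWN1", "UNKNOWN2"])
    assert ranking.full == [] and ranking.top == []
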