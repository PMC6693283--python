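"""Annotate network nodes from local tables and rank pathways.

The store is built from three flat TSVs (gene info, gene-pathway,
gene-disease).  Each node gets a pop-up-style record; pathways are
ranked by how many distinct network genes they contain and the ten
largest are returned (the full list can be exported).
"""

import tempfile
from pathlib import Path

from netdyn import load_annotations, rank_pathways

GENE_INFO = """\
TLR4\t7099\tARMD10|CD284\tprotein-coding
CXCL2\t2920\tGRO2|GROb\tprotein-coding
FN1\t2335\tCIG|ED-B\tprotein-coding
CCL4\t6351\tACT2|LAG1\tprotein-coding
"""
GENE_PATHWAY = """\
TLR4\tToll-like receptor signaling
TLR4\tNF-kB signaling
CXCL2\tNF-kB signaling
CCL4\tNF-kB signaling
CCL4\tChemokine signaling
FN1\tFocal adhesion
"""
GENE_DISEASE = "TLR4\tLiver Cirrhosis\nFN1\tFibrosis\n"

with tempfile.TemporaryDirectory() as workdir:
    base = Path(workdir)
    (base / "gene_info.tsv").write_text(GENE_INFO, encoding="utf-8")
    (base / "gene_pathway.tsv").write_text(GENE_PATHWAY, encoding="utf-8")
    (base / "gene_disease.tsv").write_text(GENE_DISEASE, encoding="utf-8")

    store = load_annotations(
        "Homo sapiens",
        base / "gene_info.tsv",
        base / "gene_pathway.tsv",
        base / "gene_disease.tsv",
    )

    record = store.node_info("TLR4")
    print(f"TLR4: entrez {record.entrez_id}, synonyms {record.synonyms},")
    print(f"      pathways {record.pathways}, diseases {record.diseases}")
    print(f"unknown id annotated? {store.node_info('XYZ123').annotated}\n")

    network_genes = ["TLR4", "CXCL2", "CCL4", "FN1"]
    ranking = rank_pathways(store, network_genes)
    print("pathway ranking (distinct network genes, ties alphabetical):")
    for pathway, count, genes in ranking.top:
        print(f"  {count}  {pathway}  [{', '.join(genes)}]")
    print("\nNF-kB signaling tops the table: 3 of the 4 network genes belong to it.")
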