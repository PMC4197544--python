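"""Hypergeometric term enrichment of the pooled-switch gene list against the
annotated array universe; the planted enriched terms should lead the table.
"""

from pathlib import Path

import pandas as pd

from axiswitch import de, enrich, io

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    sim = ROOT / "synthetic"
    expression = io.read_expression(ROOT / "expression.tsv")
    annotation = pd.read_csv(sim / "annotation.tsv", sep="\t").fillna("")
    gene_of = annotation.set_index("probeset_id")["gene_id"]

    pooled = pd.read_csv(ROOT / "contrasts" / "switch_pooled.tsv", sep="\t", index_col=0)
    calls = de.gene_level_calls(pooled, gene_of)
    sig_genes = set(calls.index[calls["significant"]])
    universe = enrich.build_universe(gene_of, expression)
    terms = io.read_gmt(sim / "terms.gmt")

    table = enrich.hypergeometric_enrichment(sig_genes, terms, universe)
    table.to_csv(ROOT / "enrichment.tsv", sep="\t", index=False)
    print(f"universe {len(universe)} genes; list {len(sig_genes)} significant genes")
    print(table.head(5).to_string(index=False))
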