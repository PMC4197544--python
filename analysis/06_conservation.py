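"""Cross-species conserved-cohort test.

Builds a 65-gene foreign cohort (species-B identifiers) biased toward true
switch genes, maps it onto the array through the ortholog table, and asks
whether its overlap with genes significant in at least one tissue comparison
beats a permutation null.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from axiswitch import conservation as cons
from axiswitch import de, enrich, io

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT_SIZE = 65

if __name__ == "__main__":
    sim = ROOT / "synthetic"
    expression = io.read_expression(ROOT / "expression.tsv")
    annotation = pd.read_csv(sim / "annotation.tsv", sep="\t").fillna("")
    gene_of = annotation.set_index("probeset_id")["gene_id"]
    orthologs = pd.read_csv(sim / "orthologs.tsv", sep="\t")
    truth = json.loads((sim / "truth.json").read_text())

    gene_calls = {}
    for name in ("PNT_vs_SZ", "CNT_vs_PNT", "RNT_vs_CNT"):
        df = pd.read_csv(ROOT / "contrasts" / f"{name}.tsv", sep="\t", index_col=0)
        gene_calls[name] = de.gene_level_calls(df, gene_of)
    sig_genes = cons.significant_in_any_comparison(gene_calls)
    universe = enrich.build_universe(gene_of, expression)

    # foreign cohort: species-B partners of switch genes plus random fill
    rng = np.random.default_rng(6)
    probesets = pd.DataFrame(truth["probesets"]).set_index("probeset_id")
    gene_map = pd.Series(truth["gene_map"])
    switch_genes = sorted(set(gene_map[probesets.index[probesets["is_switch"]]]))
    partner_of = dict(zip(truth["ortholog_truth"]["gene_A"], truth["ortholog_truth"]["gene_B"]))
    conserved = [partner_of[g] for g in switch_genes if g in partner_of][: COHORT_SIZE // 2]
    others = sorted(set(partner_of.values()) - set(conserved))
    cohort = conserved + list(rng.choice(others, COHORT_SIZE - len(conserved), replace=False))

    mapped, unmapped = cons.map_cross_species_cohort(cohort, orthologs, universe)
    result = cons.permutation_overlap_test(mapped, sig_genes, universe, B=9999, seed=6)
    blob = {
        "cohort": COHORT_SIZE, "mapped": result.cohort_size, "unmapped": len(unmapped),
        "overlap": result.overlap, "B": result.B, "p_empirical": result.p_empirical,
        "p_hypergeom": result.p_hypergeom, "null_mean": result.null_mean,
        "null_quantiles": result.null_quantiles,
    }
    (ROOT / "conservation.json").write_text(json.dumps(blob, indent=1))
    print(
        f"{result.overlap} of {result.cohort_size} mapped cohort genes significant in "
        f">=1 comparison (null mean {result.null_mean:.1f}); "
        f"p_empirical={result.p_empirical:.4g}, exact tail={result.p_hypergeom:.3g}"
    )
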