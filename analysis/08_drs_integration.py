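"""DRS/array integration: per-gene read counts, coverage-walk 3'UTR
extension (recovering planted truncations up to 7 kb), and the Pearson
correlation between platforms before and after re-annotation.
"""

import json
from pathlib import Path

import pandas as pd

from axiswitch import drs, io

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    sim = ROOT / "synthetic"
    models = io.read_gff3_models(sim / "models.gff3")
    reads = io.read_bed(sim / "reads.bed")
    truth = json.loads((sim / "truth.json").read_text())
    planted = pd.Series(truth["utr_extensions"])

    before = drs.quantify_gene_reads(models, reads)
    extended, exts = drs.extend_all(models, reads)
    after = drs.quantify_gene_reads(extended, reads)
    io.write_gff3_models(extended, ROOT / "models_extended.gff3")
    table = pd.DataFrame(
        {"count_before": before, "count_after": after,
         "extension_bp": exts, "planted_bp": planted}
    )
    table.to_csv(ROOT / "drs_gene_counts.tsv", sep="\t")
    n_ext = int((exts > 0).sum())
    exact = bool((exts.reindex(planted.index) == planted).all())
    print(f"extended {n_ext}/{len(exts)} genes, max {int(exts.max())} bp; "
          f"planted extensions recovered exactly: {exact}")

    # correlate platforms: array side = the per-gene expression the reads
    # were generated from (log2), DRS side = log2(count + 1)
    import numpy as np

    array_log2 = np.log2(pd.Series(truth["drs_expression"]) + 1)
    pairs_b = pd.DataFrame({"array_log2": array_log2, "drs_log2": np.log2(before + 1)})
    pairs_a = pd.DataFrame({"array_log2": array_log2, "drs_log2": np.log2(after + 1)})
    r_before, n = drs.correlate_platforms(pairs_b)
    r_after, _ = drs.correlate_platforms(pairs_a)
    print(f"platform correlation over {n} genes: R={r_before:.2f} before "
          f"re-annotation -> R={r_after:.2f} after")
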