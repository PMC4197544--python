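"""Readers and writers for the plain-text formats the pipeline exchanges.

TSV throughout for tabular data, GMT for term → gene-set annotation, BED6 for
read alignments (0-based half-open) and GFF3 for gene models (1-based
inclusive on disk, converted to 0-based half-open in memory).
"""

from __future__ import annotations

import os
import tempfile

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_intensities(path) -> pd.DataFrame:
    """Probe × sample intensity matrix; first column is the probe id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_layout(path) -> pd.Series:
    """probe_id → probeset_id mapping."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("probe_id")["probeset_id"]


def read_samples(path) -> pd.DataFrame:
    """Sample sheet indexed by sample_id with tissue and replicate columns."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict[str, set[str]]:
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(g for g in parts[2:] if g)
    return terms


def write_gmt(terms: dict[str, set[str]], path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            desc = (descriptions or {}).get(term_id, term_id)
            genes = "\t".join(sorted(terms[term_id]))
            fh.write(f"{term_id}\t{desc}\t{genes}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(reads: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in reads.columns]
    reads[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff3_models(path) -> pd.DataFrame:
    """Load gene features from GFF3 into 0-based half-open coordinates."""
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            str(path), dbpath, force=True, keep_order=True, merge_strategy="create_unique"
        )
        rows = []
        for feat in db.features_of_type("gene"):
            rows.append(
                {
                    "gene_id": feat.id,
                    "chrom": feat.seqid,
                    "start": feat.start - 1,  # GFF3 is 1-based inclusive
                    "end": feat.end,
                    "strand": feat.strand,
                }
            )
    finally:
        if os.path.exists(dbpath):
            os.unlink(dbpath)
    return pd.DataFrame(rows, columns=MODEL_COLUMNS)


def write_gff3_models(models: pd.DataFrame, path, source: str = "axiswitch") -> None:
    """Write gene models (internal 0-based half-open) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in models.itertuples():
            attrs = f"ID={row.gene_id}"
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
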