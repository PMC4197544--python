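"""DRS/array integration: read quantification, 3'UTR extension, correlation.

Direct RNA sequencing reads are 3'-biased and stranded; where contiguous
read coverage runs past an annotated gene end, the 3'UTR is extended by a
strand-aware coverage walk (gaps up to ``max_gap`` bp are bridged, the walk
stops at the next same-strand gene or at ``max_extension``).  Per-gene read
counts before/after extension feed a log-scale Pearson comparison between
platforms.  Coordinates are 0-based half-open throughout (BED convention);
GFF3 is converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import pearsonr


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def three_prime_end(self) -> int:
        """Coordinate of the annotated 3' end (end for +, start for -)."""
        return self.end if self.strand == "+" else self.start


def _models_iter(models: pd.DataFrame):
    for row in models.itertuples():
        yield GeneModel(row.gene_id, row.chrom, row.strand, int(row.start), int(row.end))


def _read_trees(reads: pd.DataFrame, strand_aware: bool) -> dict:
    trees: dict = {}
    for row in reads.itertuples():
        key = (row.chrom, row.strand) if strand_aware else (row.chrom,)
        trees.setdefault(key, IntervalTree()).addi(row.start, row.end)
    return trees


def quantify_gene_reads(
    models: pd.DataFrame, reads: pd.DataFrame, strand_aware: bool = True
) -> pd.Series:
    """Count reads overlapping each gene body (strand-matched by default)."""
    trees = _read_trees(reads, strand_aware)
    chroms = set(reads["chrom"])
    counts = {}
    warned = set()
    for gm in _models_iter(models):
        if gm.chrom not in chroms and gm.chrom not in warned:
            warnings.warn(f"no reads on chromosome {gm.chrom}")
            warned.add(gm.chrom)
        key = (gm.chrom, gm.strand) if strand_aware else (gm.chrom,)
        tree = trees.get(key)
        counts[gm.gene_id] = len(tree.overlap(gm.start, gm.end)) if tree else 0
    return pd.Series(counts, name="count")


def _downstream_coverage(
    gm: GeneModel, reads: pd.DataFrame, length: int, strand_aware: bool = True
) -> np.ndarray:
    """Read coverage over ``length`` bp downstream of the annotated 3' end,
    indexed by distance from the end in the direction of transcription."""
    sel = reads["chrom"] == gm.chrom
    if strand_aware:
        sel &= reads["strand"] == gm.strand
    sub = reads[sel]
    cov = np.zeros(length, dtype=int)
    if gm.strand == "+":
        lo, hi = gm.end, gm.end + length
        for row in sub.itertuples():
            a, b = max(row.start, lo), min(row.end, hi)
            if a < b:
                cov[a - lo : b - lo] += 1
    else:
        lo, hi = gm.start - length, gm.start
        for row in sub.itertuples():
            a, b = max(row.start, lo), min(row.end, hi)
            if a < b:
                # offset 0 is the base immediately downstream (hi - 1)
                cov[hi - b : hi - a] += 1
    return cov


def _next_gene_distance(gm: GeneModel, models: pd.DataFrame) -> int | None:
    """bp from the annotated 3' end to the nearest same-strand downstream gene."""
    same = models[
        (models["chrom"] == gm.chrom)
        & (models["strand"] == gm.strand)
        & (models["gene_id"] != gm.gene_id)
    ]
    if gm.strand == "+":
        downstream = same[same["start"] >= gm.end]
        return int((downstream["start"] - gm.end).min()) if len(downstream) else None
    downstream = same[same["end"] <= gm.start]
    return int((gm.start - downstream["end"]).min()) if len(downstream) else None


def extend_three_prime_utr(
    model: GeneModel,
    reads: pd.DataFrame,
    max_gap: int = 50,
    min_cov: int = 1,
    max_extension: int = 10000,
    next_gene_distance: int | None = None,
) -> tuple[GeneModel, int, str]:
    """Extend the 3' end through contiguous downstream coverage.

    Walks base-by-base downstream of the annotated 3' end; positions with
    coverage >= ``min_cov`` extend the UTR, uncovered runs longer than
    ``max_gap`` stop the walk.  The extension is capped by ``max_extension``
    and by the next same-strand gene.  Returns (possibly extended model,
    extension length, reason-the-walk-stopped).
    """
    if min(max_gap, min_cov, max_extension) < 0:
        raise ValueError("parameters must be >= 0")
    limit = max_extension
    reason = "max_extension reached"
    if next_gene_distance is not None and next_gene_distance < limit:
        limit = next_gene_distance
        reason = "downstream gene boundary"
    if limit == 0:
        return model, 0, "abutting downstream gene" if next_gene_distance == 0 else "zero limit"

    cov = _downstream_coverage(model, reads, limit)
    ext = 0
    gap_run = 0
    for offset in range(limit):
        if cov[offset] >= min_cov:
            ext = offset + 1
            gap_run = 0
        else:
            gap_run += 1
            if gap_run > max_gap:
                reason = "coverage gap exceeded max_gap"
                break
    else:
        pass  # walked to the limit; reason already set
    if ext == 0:
        return model, 0, "no downstream coverage"
    if model.strand == "+":
        extended = replace(model, end=model.end + ext)
    else:
        extended = replace(model, start=model.start - ext)
    return extended, ext, reason


def extend_all(
    models: pd.DataFrame,
    reads: pd.DataFrame,
    max_gap: int = 50,
    min_cov: int = 1,
    max_extension: int = 10000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the coverage walk to every gene; returns (extended models,
    per-gene extension lengths)."""
    out_rows = []
    exts = {}
    for gm in _models_iter(models):
        dist = _next_gene_distance(gm, models)
        extended, ext, _ = extend_three_prime_utr(
            gm, reads, max_gap=max_gap, min_cov=min_cov,
            max_extension=max_extension, next_gene_distance=dist,
        )
        exts[gm.gene_id] = ext
        out_rows.append(
            {"gene_id": extended.gene_id, "chrom": extended.chrom,
             "start": extended.start, "end": extended.end, "strand": extended.strand}
        )
    return (
        pd.DataFrame(out_rows, columns=["gene_id", "chrom", "start", "end", "strand"]),
        pd.Series(exts, name="extension_bp"),
    )


def correlate_platforms(pairs: pd.DataFrame, x: str = "array_log2", y: str = "drs_log2"):
    """Pearson R between paired log-scale platform measurements.

    Returns (R, n).  Requires n >= 3 and non-degenerate variance on both
    axes.
    """
    sub = pairs[[x, y]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.isclose(sub[x].var(), 0) or np.isclose(sub[y].var(), 0):
        raise ValueError("zero variance in one platform; correlation undefined")
    r, _ = pearsonr(sub[x], sub[y])
    return float(r), n


def platform_pairs(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: pd.Series,
    drs_counts: pd.Series,
    tissue: str = "PNT",
) -> pd.DataFrame:
    """Pair per-gene array expression (mean log2 over a tissue's replicates,
    probe-sets averaged within gene) with log2(DRS count + 1)."""
    cols = samples.index[samples["tissue"] == tissue]
    mean_expr = expression[cols].mean(axis=1)
    genes = annotation.reindex(expression.index)
    per_gene = mean_expr.groupby(genes).mean()
    common = sorted(set(per_gene.index) & set(drs_counts.index))
    return pd.DataFrame(
        {
            "array_log2": per_gene.reindex(common),
            "drs_log2": np.log2(drs_counts.reindex(common).astype(float) + 1.0),
        },
        index=pd.Index(common, name="gene_id"),
    )
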