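"""Hypergeometric over-representation of term annotations in gene lists.

Tests are gene-level (probe-sets collapsed to genes first, so probe-set
redundancy cannot inflate overlaps) against the universe of genes annotated
on the array — the standard "gene universe" convention.  Flat term tests
only; no GO-graph decorrelation.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_fdr


def build_universe(annotation: pd.Series, expression: pd.DataFrame) -> list[str]:
    """Genes with at least one annotated probe-set on the array, deduplicated.

    ``annotation`` maps probeset_id → gene_id; unannotated probe-sets (empty
    or null gene) are excluded.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    on_array = annotation.reindex(expression.index).dropna()
    on_array = on_array[on_array != ""]
    universe = sorted(set(on_array))
    if not universe:
        raise ValueError("empty gene universe: no annotated probe-sets on the array")
    return universe


def hypergeometric_enrichment(
    sig_genes, terms: dict[str, set[str]], universe, with_q: bool = True
) -> pd.DataFrame:
    """Exact upper-tail hypergeometric test per term.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n) where N is the universe
    size, K the term size within the universe, n the significant-list size
    and k the overlap.  Significant genes outside the universe are dropped
    with a warning; terms with no gene in the universe are skipped.
    """
    universe_set = set(universe)
    sig = set(sig_genes)
    outside = sig - universe_set
    if outside:
        warnings.warn(
            f"dropping {len(outside)} significant genes outside the universe"
        )
        sig &= universe_set
    N, n = len(universe_set), len(sig)
    rows = []
    for term_id in sorted(terms):
        members = set(terms[term_id]) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & sig)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k), exact
        rows.append(
            {"term_id": term_id, "N": N, "K": K, "n": n, "k": k, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term_id", "N", "K", "n", "k", "p"])
    if with_q and len(out):
        out["q"] = bh_fdr(out["p"].values)
    return out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
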