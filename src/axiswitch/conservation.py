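"""Cross-species conserved-cohort test.

A foreign gene cohort (e.g. the 65 Drosophila RNA-processing / cell-cycle
genes downregulated at post-gastrula stages) is mapped onto array genes via
an ortholog table; the overlap with genes significant in at least one
tissue comparison is compared with a permutation null of equal-size random
draws from the gene universe.  An exact hypergeometric tail is reported
alongside the empirical p for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def map_cross_species_cohort(
    cohort,
    orthologs: pd.DataFrame,
    array_genes,
    source_col: str = "gene_B",
    target_col: str = "gene_A",
) -> tuple[set[str], list[str]]:
    """Map a foreign cohort to array genes through the ortholog table.

    Each cohort member contributes the union of its ortholog targets present
    on the array (a 1:2 ortholog adds both).  Returns (mapped array genes,
    cohort members with no mapped ortholog).
    """
    array_set = set(array_genes)
    by_source = orthologs.groupby(source_col)[target_col].agg(set)
    mapped: set[str] = set()
    unmapped: list[str] = []
    for g in cohort:
        targets = by_source.get(g, set()) & array_set
        if targets:
            mapped |= targets
        else:
            unmapped.append(g)
    if not mapped:
        warnings.warn("no cohort member mapped to the array")
    return mapped, unmapped


@dataclass
class ConservedCohortResult:
    cohort_size: int  # mapped cohort size m
    overlap: int  # k: cohort genes significant in >= 1 comparison
    B: int
    p_empirical: float
    p_hypergeom: float
    null_mean: float
    null_quantiles: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def permutation_overlap_test(
    mapped_cohort,
    significant_genes,
    universe,
    B: int = 9999,
    seed: int = 0,
) -> ConservedCohortResult:
    """Empirical p for the cohort/significant-gene overlap.

    Null: B uniform draws of |cohort| genes from the universe;
    p = (#{null overlap >= k} + 1)/(B + 1), so the attainable floor is
    1/(B + 1) — 0.001 at B = 999.  Seed-reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = sorted(set(universe))
    cohort = sorted(set(mapped_cohort))
    outside = set(cohort) - set(universe)
    if outside:
        raise ValueError(f"cohort not contained in universe: {sorted(outside)[:5]}")
    m, N = len(cohort), len(universe)
    if m > N:
        raise ValueError("cohort larger than universe")
    sig = set(significant_genes) & set(universe)
    k = len(set(cohort) & sig)

    is_sig = np.array([g in sig for g in universe])
    rng = np.random.default_rng(seed)
    # vectorized subset draws when the index matrix is small enough
    if m == 0:
        null = np.zeros(B, dtype=int)
    elif B * N <= 50_000_000:
        keys = rng.random((B, N))
        draws = np.argpartition(keys, m - 1, axis=1)[:, :m] if m < N else np.tile(
            np.arange(N), (B, 1)
        )
        null = is_sig[draws].sum(axis=1)
    else:
        null = np.empty(B, dtype=int)
        for b in range(B):
            null[b] = is_sig[rng.choice(N, size=m, replace=False)].sum()
    exceed = int((null >= k).sum())
    p_emp = (exceed + 1) / (B + 1)
    p_hyp = float(hypergeom.sf(k - 1, N, len(sig), m))
    qs = {f"q{q}": float(np.percentile(null, q)) for q in (5, 25, 50, 75, 95)}
    return ConservedCohortResult(
        cohort_size=m,
        overlap=k,
        B=B,
        p_empirical=p_emp,
        p_hypergeom=p_hyp,
        null_mean=float(null.mean()),
        null_quantiles=qs,
    )


def significant_in_any_comparison(
    gene_calls: dict[str, pd.DataFrame], include: list[str] | None = None
) -> set[str]:
    """Union of significant genes over the named tissue comparisons.

    By default the three pairwise transition contrasts are used (the pooled
    switch contrast is excluded; pass ``include`` to change the set).
    """
    names = include if include is not None else ["PNT_vs_SZ", "CNT_vs_PNT", "RNT_vs_CNT"]
    out: set[str] = set()
    for name in names:
        df = gene_calls[name]
        out |= set(df.index[df["significant"]])
    return out
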