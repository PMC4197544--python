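"""Probe-set re-annotation and ortholog resolution.

Poorly annotated probe-sets are assigned genes through an evidence cascade:
vendor annotation, then EST/cDNA chaining, then cross-species orthology
resolved by conserved gene order (synteny), then protein-similarity hits
from a precomputed search.  The cascade order is total and enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EVIDENCE_ORDER = ("vendor", "est_chain", "ortholog_synteny", "similarity")


def _is_null(g) -> bool:
    return g is None or (isinstance(g, float) and np.isnan(g)) or g == ""


def map_probesets_to_genes(
    vendor: pd.DataFrame, est_to_gene: pd.DataFrame
) -> pd.DataFrame:
    """Vendor annotation first; else chain ESTs to a gene.

    A probe-set whose ESTs map to more than one gene is left unresolved and
    flagged as a conflict.  Columns in: vendor(probeset_id, gene_id,
    est_ids comma-joined); est_to_gene(est_id, gene_id).
    """
    est_map = est_to_gene.set_index("est_id")["gene_id"] if len(est_to_gene) else pd.Series(dtype=object)
    rows = []
    for row in vendor.itertuples():
        ests = [e for e in str(getattr(row, "est_ids", "") or "").split(",") if e]
        if not _is_null(row.gene_id):
            rows.append(
                {"probeset_id": row.probeset_id, "gene_id": row.gene_id,
                 "evidence": "vendor", "est_ids": ",".join(ests), "conflict": False}
            )
            continue
        genes = sorted({est_map[e] for e in ests if e in est_map.index})
        if len(genes) == 1:
            rows.append(
                {"probeset_id": row.probeset_id, "gene_id": genes[0],
                 "evidence": "est_chain", "est_ids": ",".join(ests), "conflict": False}
            )
        else:
            rows.append(
                {"probeset_id": row.probeset_id, "gene_id": None, "evidence": None,
                 "est_ids": ",".join(ests), "conflict": len(genes) > 1}
            )
    return pd.DataFrame(rows)


def _positions(orders: dict[str, list[str]]) -> dict[str, tuple[str, int]]:
    pos: dict[str, tuple[str, int]] = {}
    for chrom, genes in orders.items():
        for rank, g in enumerate(genes):
            if g in pos:
                raise ValueError(f"gene {g} appears twice in the order map")
            pos[g] = (chrom, rank)
    return pos


def _neighbours(gene: str, pos, orders, window: int) -> list[str]:
    if gene not in pos:
        return []
    chrom, rank = pos[gene]
    genes = orders[chrom]
    lo, hi = max(0, rank - window), min(len(genes), rank + window + 1)
    return [g for g in genes[lo:hi] if g != gene]


def _synteny_score(
    gene_a: str, cand_b: str, accepted: dict[str, str],
    pos_a, orders_a, pos_b, orders_b, window: int,
) -> int:
    """Count of ±window neighbours of gene_a whose accepted ortholog lies
    within ±window of cand_b."""
    if cand_b not in pos_b:
        warnings.warn(f"candidate {cand_b} absent from gene order map; scored 0")
        return 0
    if gene_a not in pos_a:
        warnings.warn(f"gene {gene_a} absent from gene order map; candidates scored 0")
        return 0
    near_b = set(_neighbours(cand_b, pos_b, orders_b, window))
    score = 0
    for nb in _neighbours(gene_a, pos_a, orders_a, window):
        partner = accepted.get(nb)
        if partner is not None and partner in near_b:
            score += 1
    return score


@dataclass
class SyntenyResolution:
    resolved: pd.DataFrame  # gene_A, gene_B, method, score, margin
    unresolved: pd.DataFrame  # gene_A, candidates, reason


def resolve_orthologs_by_synteny(
    table: pd.DataFrame,
    orders_a: dict[str, list[str]],
    orders_b: dict[str, list[str]],
    window: int = 5,
    min_margin: int = 1,
) -> SyntenyResolution:
    """Resolve ambiguous ortholog rows by conserved gene order.

    1:1 rows pass through as accepted anchors.  Ambiguous source genes are
    resolved greedily: every candidate is scored by shared ordered
    neighbours; the globally highest-margin assignment (best minus
    runner-up, ties broken lexicographically) is fixed, its genes removed
    from other candidate lists, scores recomputed — so late resolutions can
    lean on earlier ones.  A source whose best margin stays below
    ``min_margin`` is left unresolved; no guessing on ties.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    pos_a, pos_b = _positions(orders_a), _positions(orders_b)

    count_a = table["gene_A"].value_counts()
    count_b = table["gene_B"].value_counts()
    unambiguous = table[
        table["gene_A"].map(count_a).eq(1) & table["gene_B"].map(count_b).eq(1)
    ]
    accepted: dict[str, str] = dict(zip(unambiguous["gene_A"], unambiguous["gene_B"]))
    resolved_rows = [
        {"gene_A": a, "gene_B": b, "method": "one_to_one", "score": np.nan, "margin": np.nan}
        for a, b in sorted(accepted.items())
    ]

    ambiguous = table.drop(index=unambiguous.index)
    candidates: dict[str, list[str]] = {}
    for row in ambiguous.itertuples():
        candidates.setdefault(row.gene_A, []).append(row.gene_B)
    taken_b: set[str] = set()

    while candidates:
        best_pick = None  # (margin, gene_A, gene_B, score)
        scored: dict[str, list[tuple[int, str]]] = {}
        for a, cands in candidates.items():
            live = [b for b in cands if b not in taken_b]
            pairs = sorted(
                ((_synteny_score(a, b, accepted, pos_a, orders_a, pos_b, orders_b, window), b)
                 for b in live),
                key=lambda sb: (-sb[0], sb[1]),
            )
            scored[a] = pairs
            if not pairs:
                continue
            top_score, top_b = pairs[0]
            runner = pairs[1][0] if len(pairs) > 1 else 0
            margin = top_score - runner
            if margin >= min_margin:
                key = (-margin, a, top_b)
                if best_pick is None or key < (-best_pick[0], best_pick[1], best_pick[2]):
                    best_pick = (margin, a, top_b, top_score)
        if best_pick is None:
            break
        margin, a, b, score = best_pick
        accepted[a] = b
        taken_b.add(b)
        resolved_rows.append(
            {"gene_A": a, "gene_B": b, "method": "synteny", "score": score, "margin": margin}
        )
        del candidates[a]

    unresolved_rows = [
        {
            "gene_A": a,
            "candidates": ",".join(sorted(set(c for c in cands if c not in taken_b))),
            "reason": "no candidate exceeds runner-up by min_margin"
            if any(b not in taken_b for b in cands)
            else "all candidates consumed",
        }
        for a, cands in sorted(candidates.items())
    ]
    return SyntenyResolution(
        resolved=pd.DataFrame(
            resolved_rows, columns=["gene_A", "gene_B", "method", "score", "margin"]
        ),
        unresolved=pd.DataFrame(unresolved_rows, columns=["gene_A", "candidates", "reason"]),
    )


def assign_by_similarity(
    unannotated,
    hits: pd.DataFrame,
    min_identity: float = 90.0,
    max_evalue: float = 1e-5,
) -> pd.DataFrame:
    """Assign each still-unannotated probe-set the gene of its best passing
    protein hit; equal-best hits to different genes leave it unresolved.

    ``hits`` columns: probeset_id, protein_id, gene_id, identity, length,
    evalue.
    """
    want = set(unannotated)
    passing = hits[
        hits["probeset_id"].isin(want)
        & (hits["identity"] >= min_identity)
        & (hits["evalue"] <= max_evalue)
    ]
    rows = []
    for ps, group in passing.groupby("probeset_id"):
        best = group[group["identity"] == group["identity"].max()]
        genes = sorted(set(best["gene_id"]))
        if len(genes) != 1:
            continue  # ambiguous top hit: no guessing
        rows.append(
            {"probeset_id": ps, "gene_id": genes[0], "evidence": "similarity",
             "est_ids": "", "conflict": False}
        )
    return pd.DataFrame(
        rows, columns=["probeset_id", "gene_id", "evidence", "est_ids", "conflict"]
    )


def merge_evidence(*frames: pd.DataFrame) -> pd.DataFrame:
    """Combine annotation frames, keeping the highest-precedence evidence
    (vendor > est_chain > ortholog_synteny > similarity) per probe-set."""
    rank = {e: i for i, e in enumerate(EVIDENCE_ORDER)}
    merged = pd.concat([f for f in frames if len(f)], ignore_index=True)
    merged = merged[~merged["gene_id"].map(_is_null)]
    merged["_rank"] = merged["evidence"].map(rank)
    merged = merged.sort_values(["probeset_id", "_rank"], kind="stable")
    return merged.drop_duplicates("probeset_id", keep="first").drop(columns="_rank").reset_index(drop=True)


def annotation_coverage_report(
    before: pd.DataFrame,
    after: pd.DataFrame,
    significant_lists: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Counts and fractions of annotated probe-sets before vs after
    re-annotation, overall and within each significant probe-set list."""
    def annotated_set(df):
        ok = ~df["gene_id"].map(_is_null)
        return set(df.loc[ok, "probeset_id"])

    b, a = annotated_set(before), annotated_set(after)
    all_ps = list(before["probeset_id"])
    scopes = {"all": set(all_ps)}
    for name, ps in (significant_lists or {}).items():
        scopes[name] = set(ps)
    rows = []
    for name, scope in scopes.items():
        n = len(scope)
        rows.append(
            {
                "scope": name,
                "n_probesets": n,
                "annotated_before": len(b & scope),
                "annotated_after": len(a & scope),
                "newly_annotated": len((a - b) & scope),
                "frac_unannotated_before": (n - len(b & scope)) / n if n else np.nan,
                "frac_unannotated_after": (n - len(a & scope)) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("scope")
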