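"""RMA-style probe-level processing.

Background handling, quantile normalization, and Tukey median-polish
summarization from probe-level intensities to one log2 expression value per
probe-set and sample, plus replicate QC by hierarchical clustering and the
mean-scaled relative log10 expression profiles used to visualise the
transcriptome switch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .simulate import TISSUES, ProbeIntensityMatrix

#: clamp floor applied after background shift, log2(eps) ≈ -20
_EPSILON = 2.0**-20


def background_correct(
    intensities: pd.DataFrame, mode: str = "none", percentile: float = 1.0
) -> pd.DataFrame:
    """Per-array background handling.

    mode="none" returns the input unchanged (the default: downstream
    statistics are the analysis surface, and background choice is isolated
    here for users running real scanner-derived matrices).  mode="shift_log"
    subtracts a per-array percentile floor and clamps to a small positive
    epsilon so the log transform stays finite.
    """
    if (intensities.values <= 0).any():
        raise ValueError("intensities must be strictly positive")
    if mode == "none":
        return intensities
    if mode == "shift_log":
        floor = np.percentile(intensities.values, percentile, axis=0)
        shifted = intensities.values - floor[None, :]
        return pd.DataFrame(
            np.maximum(shifted + _EPSILON, _EPSILON),
            index=intensities.index,
            columns=intensities.columns,
        )
    raise ValueError(f"unknown background mode: {mode!r}")


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common reference distribution.

    The reference is the vector of row-wise means of the column-sorted
    values.  Tied values within a column receive the mean of the reference
    quantiles they span (average-rank convention), so the result is
    idempotent and permutation-equivariant in columns.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    values = m.values.astype(float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = pd.Series(values[:, j]).rank(method="average").values  # 1-based
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def median_polish(table: np.ndarray, max_iter: int = 20, tol: float = 1e-6):
    """Tukey median polish of an additive two-way table, row sweep first.

    Returns (overall, row_effects, col_effects, residuals).  Iterates until
    the total absolute residual changes by less than ``tol`` (relative) or
    ``max_iter`` sweeps.  Results depend on sweep order; row-first is fixed
    here and documented.
    """
    stack = np.asarray(table, dtype=float)[None, :, :]
    overall, row_eff, col_eff, resid = _median_polish_stack(stack, max_iter=max_iter, tol=tol)
    return overall[0], row_eff[0], col_eff[0], resid[0]


def _median_polish_stack(stack: np.ndarray, max_iter: int = 20, tol: float = 1e-6):
    """Vectorized row-first median polish over a (groups, rows, cols) stack."""
    g, _, m = stack.shape
    resid = stack.astype(float).copy()
    overall = np.zeros(g)
    row_eff = np.zeros(stack.shape[:2])
    col_eff = np.zeros((g, m))
    prev_total = np.abs(resid).sum(axis=(1, 2))
    scale = np.where(prev_total > 0, prev_total, 1.0)
    for _ in range(max_iter):
        row_med = np.median(resid, axis=2)
        resid -= row_med[:, :, None]
        row_eff += row_med
        delta = np.median(col_eff, axis=1)
        col_eff -= delta[:, None]
        overall += delta

        col_med = np.median(resid, axis=1)
        resid -= col_med[:, None, :]
        col_eff += col_med
        delta = np.median(row_eff, axis=1)
        row_eff -= delta[:, None]
        overall += delta

        total = np.abs(resid).sum(axis=(1, 2))
        if np.all(np.abs(prev_total - total) < tol * scale):
            break
        prev_total = total
    return overall, row_eff, col_eff, resid


def medianpolish_summarize(log2_intensities: pd.DataFrame, layout: pd.Series) -> pd.DataFrame:
    """Summarize log2 probe intensities to probe-set expression.

    Per probe-set, fits log2(intensity) = probeset_effect + sample_effect +
    probe_effect + residual by median polish; the reported expression is
    overall + sample effects.  Probe-sets are polished in batches of equal
    probe count so the sweep is fully vectorized.
    """
    probesets = layout.reindex(log2_intensities.index)
    if probesets.isna().any():
        raise ValueError("layout is missing probes present in the matrix")
    order = {}
    for probe, ps in probesets.items():
        order.setdefault(ps, []).append(probe)
    if any(len(v) == 0 for v in order.values()):
        raise ValueError("empty probe-set")

    sizes: dict[int, list[str]] = {}
    for ps, probes in order.items():
        sizes.setdefault(len(probes), []).append(ps)

    values = log2_intensities
    rows = {}
    for k, ps_list in sizes.items():
        idx = [p for ps in ps_list for p in order[ps]]
        stack = values.loc[idx].values.reshape(len(ps_list), k, values.shape[1])
        overall, _, col_eff, _ = _median_polish_stack(stack)
        expr = overall[:, None] + col_eff
        for i, ps in enumerate(ps_list):
            rows[ps] = expr[i]

    ps_order = sorted(rows)
    out = pd.DataFrame(
        np.vstack([rows[ps] for ps in ps_order]),
        index=pd.Index(ps_order, name="probeset_id"),
        columns=values.columns,
    )
    return out


def rma(
    pim: ProbeIntensityMatrix, background: str = "none", percentile: float = 1.0
) -> pd.DataFrame:
    """Full chain: background → quantile normalization → log2 → median polish."""
    corrected = background_correct(pim.intensities, mode=background, percentile=percentile)
    normalized = quantile_normalize(corrected)
    return medianpolish_summarize(np.log2(normalized), pim.layout)


def relative_expression_profiles(
    expression: pd.DataFrame, samples: pd.DataFrame, probesets=None
) -> pd.DataFrame:
    """Mean-scaled relative log10 expression profile per probe-set.

    I_{p,t} is the (linear-scale) intensity of probe-set p averaged across
    the replicates of tissue t; <I_p> averages across all replicates of all
    tissues.  The profile is log10(I_{p,t} / <I_p>) over the four tissues,
    so with equal replicate counts the linear-scale profile averages to 1.
    """
    missing = [t for t in TISSUES if t not in set(samples["tissue"])]
    if missing:
        raise ValueError(f"sample sheet lacks tissues: {missing}")
    if probesets is not None:
        absent = set(probesets) - set(expression.index)
        if absent:
            raise KeyError(f"probe-sets not in expression matrix: {sorted(absent)[:5]}")
        expression = expression.loc[list(probesets)]
    linear = np.exp2(expression)
    tissue_means = {
        t: linear[samples.index[samples["tissue"] == t]].mean(axis=1) for t in TISSUES
    }
    grand = linear.mean(axis=1)
    return pd.DataFrame({t: np.log10(tissue_means[t] / grand) for t in TISSUES})


def cluster_replicates(expression: pd.DataFrame, samples: pd.DataFrame):
    """Average-linkage clustering on correlation distance with replicate QC.

    Flags any sample whose nearest neighbour (1 - Pearson) belongs to a
    different tissue.  Returns (linkage matrix, per-sample report, passed).
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two samples")
    corr = np.corrcoef(expression.values.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")

    rows = []
    sample_ids = list(expression.columns)
    tissues = samples.loc[sample_ids, "tissue"].values
    for i, sid in enumerate(sample_ids):
        d = dist[i].copy()
        d[i] = np.inf
        j = int(np.argmin(d))
        rows.append(
            {
                "sample_id": sid,
                "tissue": tissues[i],
                "nearest": sample_ids[j],
                "nearest_tissue": tissues[j],
                "ok": (tissues[i] == tissues[j]) or len(sample_ids) == 2,
            }
        )
    report = pd.DataFrame(rows).set_index("sample_id")
    return Z, report, bool(report["ok"].all())
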