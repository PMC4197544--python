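"""Moderated linear-model contrasts along the neural axis.

Per-probe-set group-means linear models over the ordered tissues, pairwise
transition contrasts plus the pooled "differentiation switch" contrast
(mean(CNT,RNT) - mean(SZ,PNT)), empirical-Bayes variance moderation in the
limma style (scaled-F prior estimated by method of moments on log s^2),
Benjamini-Hochberg q-values, significance calling at the strict q < 0.046
threshold, and a permutation screen for sex-linked bias over CASI
(cell-autonomous sex identity) genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

Q_THRESHOLD = 0.046  # strict: q must be < this to call a probe-set regulated

_S2_FLOOR = np.finfo(float).eps


@dataclass
class ContrastSpec:
    """Named linear contrast over group means; coefficients must sum to 0."""

    name: str
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.coefficients.values())) > 1e-12:
            raise ValueError(f"contrast {self.name!r} coefficients must sum to 0")

    def vector(self, groups: list[str]) -> np.ndarray:
        return np.array([self.coefficients.get(g, 0.0) for g in groups])


def standard_contrasts(include_interaction: bool = False) -> list[ContrastSpec]:
    """The three transition contrasts and the pooled switch contrast.

    The pooled contrast compares the combined SZ+PNT replicates against the
    combined CNT+RNT replicates (a 6-vs-6 two-group comparison when each
    tissue has 3 replicates).  The optional interaction contrast
    (CNT-PNT)-(PNT-SZ) asks whether the step at the switch exceeds the
    preceding drift.
    """
    contrasts = [
        ContrastSpec("PNT_vs_SZ", {"PNT": 1.0, "SZ": -1.0}),
        ContrastSpec("CNT_vs_PNT", {"CNT": 1.0, "PNT": -1.0}),
        ContrastSpec("RNT_vs_CNT", {"RNT": 1.0, "CNT": -1.0}),
        ContrastSpec("switch_pooled", {"SZ": -0.5, "PNT": -0.5, "CNT": 0.5, "RNT": 0.5}),
    ]
    if include_interaction:
        contrasts.append(
            ContrastSpec("switch_interaction", {"SZ": 1.0, "PNT": -2.0, "CNT": 1.0})
        )
    return contrasts


@dataclass
class LinearFit:
    """Per-probe-set OLS group means with a pooled residual variance."""

    groups: list[str]
    means: pd.DataFrame  # probeset × group
    s2: pd.Series  # residual variance, df degrees of freedom
    df: int
    n_per_group: pd.Series


@dataclass
class ModerationHyperparameters:
    d0: float  # prior degrees of freedom (np.inf allowed)
    s0_2: float  # prior variance

    def posterior_variance(self, s2: pd.Series, df: int) -> pd.Series:
        if np.isinf(self.d0):
            return pd.Series(self.s0_2, index=s2.index)
        if self.d0 == 0:
            return s2.copy()
        return (self.d0 * self.s0_2 + df * s2) / (self.d0 + df)


def fit_linear_model(
    expression: pd.DataFrame, samples: pd.DataFrame, group_col: str = "tissue"
) -> LinearFit:
    """OLS cell-means fit per probe-set over an arbitrary grouping factor.

    With 4 tissues × 3 replicates the residual df is 12 - 4 = 8.
    """
    sample_ids = [s for s in expression.columns if s in samples.index]
    if len(sample_ids) != expression.shape[1]:
        missing = set(expression.columns) - set(samples.index)
        raise ValueError(f"samples sheet lacks entries for {sorted(missing)[:5]}")
    groups_of = samples.loc[sample_ids, group_col]
    groups = list(dict.fromkeys(groups_of))  # preserve first-appearance order
    n_per_group = groups_of.value_counts().reindex(groups)
    if (n_per_group < 1).any():
        raise ValueError("singular design: empty group")
    df = len(sample_ids) - len(groups)
    if df < 1:
        raise ValueError("no residual degrees of freedom; need replicates")

    values = expression[sample_ids].values
    means = np.empty((values.shape[0], len(groups)))
    rss = np.zeros(values.shape[0])
    for gi, g in enumerate(groups):
        cols = np.array([i for i, s in enumerate(sample_ids) if groups_of.iloc[i] == g])
        sub = values[:, cols]
        mu = sub.mean(axis=1)
        means[:, gi] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)

    return LinearFit(
        groups=groups,
        means=pd.DataFrame(means, index=expression.index, columns=groups),
        s2=pd.Series(rss / df, index=expression.index, name="s2"),
        df=df,
        n_per_group=n_per_group,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(
    s2: pd.Series, df: int, d0_override: float | None = None
) -> tuple[ModerationHyperparameters, pd.Series]:
    """Estimate a scaled-F prior for residual variances and shrink toward it.

    Under s^2 ~ s0^2 * chi^2_df / df given a chi^2_d0 prior, log s^2 has
    known digamma/trigamma moments; matching the sample mean and variance of
    log s^2 yields (d0, s0^2).  The posterior variance is
    (d0*s0^2 + df*s^2) / (d0 + df); if the observed log-variance dispersion
    is no larger than the chi^2 sampling noise, d0 is infinite and every
    posterior variance equals s0^2.
    """
    s2 = pd.Series(s2).astype(float)
    if (s2 <= 0).any():
        if (s2 <= 0).all():
            raise ValueError(
                "all residual variances are zero — zero-noise data leaves the "
                "moderated model untestable; add noise or use d0_override=0"
            )
        warnings.warn("flooring non-positive residual variances at machine epsilon")
        s2 = s2.clip(lower=_S2_FLOOR)
    if d0_override is not None:
        hyper = ModerationHyperparameters(d0=float(d0_override), s0_2=float(s2.median()))
        return hyper, hyper.posterior_variance(s2, df)
    if len(s2) < 2:
        raise ValueError("need at least two probe-sets to estimate the prior")

    z = np.log(s2.values)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    if e_var < 1e-15:
        # degenerate boundary: no dispersion at all, so no chi^2 sampling
        # scatter to deconvolve — the prior is the common value itself
        hyper = ModerationHyperparameters(d0=np.inf, s0_2=float(np.exp(z.mean())))
        return hyper, hyper.posterior_variance(s2, df)
    resid_var = e_var - polygamma(1, df / 2.0)
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(float(resid_var))
        s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    hyper = ModerationHyperparameters(d0=d0, s0_2=s0_2)
    return hyper, hyper.posterior_variance(s2, df)


def compute_contrast_stats(
    fit: LinearFit,
    contrast: ContrastSpec,
    moderation: tuple[ModerationHyperparameters, pd.Series] | None = None,
) -> pd.DataFrame:
    """Moderated t, p and logFC for one contrast.

    t = c'mu / (s_tilde * sqrt(sum c_g^2 / n_g)); two-sided p from a t
    distribution with d0 + df degrees of freedom.  With moderation=None the
    ordinary (d0 = 0) statistics are returned.
    """
    c = contrast.vector(fit.groups)
    logfc = fit.means.values @ c
    se_unscaled = float(np.sqrt(np.sum(c**2 / fit.n_per_group.values)))
    if moderation is None:
        s_tilde2 = fit.s2.clip(lower=_S2_FLOOR)
        df_total = float(fit.df)
    else:
        hyper, s_tilde2 = moderation
        s_tilde2 = s_tilde2.clip(lower=_S2_FLOOR)
        df_total = float(fit.df + hyper.d0)
    with np.errstate(divide="ignore"):
        t = logfc / (np.sqrt(s_tilde2.values) * se_unscaled)
    t = np.where(logfc == 0.0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p, "df_total": df_total}, index=fit.means.index
    )
    out["q"] = bh_fdr(out["p"])
    return out


def bh_fdr(p) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return pd.Series(dtype=float) if isinstance(p, pd.Series) else arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def call_significant(
    results: dict[str, pd.DataFrame] | pd.DataFrame, q_threshold: float = Q_THRESHOLD
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Flag probe-sets with q strictly below threshold; tabulate per contrast.

    Returns the augmented per-contrast tables and a summary with counts of
    significant probe-sets, up/down split and percent down (the switch
    contrast's down excess is the headline number).
    """
    if isinstance(results, pd.DataFrame):
        results = {"contrast": results}
    summary_rows = []
    out = {}
    for name, df in results.items():
        df = df.copy()
        if "q" not in df.columns:
            df["q"] = bh_fdr(df["p"])
        df["significant"] = df["q"] < q_threshold
        df["direction"] = np.where(df["logFC"] >= 0, "up", "down")
        n_sig = int(df["significant"].sum())
        n_down = int((df["significant"] & (df["direction"] == "down")).sum())
        summary_rows.append(
            {
                "contrast": name,
                "n_significant": n_sig,
                "n_up": n_sig - n_down,
                "n_down": n_down,
                "pct_down": 100.0 * n_down / n_sig if n_sig else np.nan,
            }
        )
        out[name] = df
    return out, pd.DataFrame(summary_rows).set_index("contrast")


def run_contrasts(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    contrasts: list[ContrastSpec] | None = None,
    q_threshold: float = Q_THRESHOLD,
    d0_override: float | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Fit, moderate, test every contrast and call significance (one stop)."""
    contrasts = contrasts if contrasts is not None else standard_contrasts()
    fit = fit_linear_model(expression, samples)
    moderation = moderate_variances(fit.s2, fit.df, d0_override=d0_override)
    results = {c.name: compute_contrast_stats(fit, c, moderation) for c in contrasts}
    return call_significant(results, q_threshold=q_threshold)


def gene_level_calls(results: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Collapse probe-set calls to genes: any significant probe-set makes the
    gene significant; direction comes from the probe-set with the smallest q
    (ties broken by larger |logFC|)."""
    df = results.copy()
    df["gene_id"] = annotation.reindex(df.index)
    df = df.dropna(subset=["gene_id"])
    df = df[df["gene_id"] != ""]
    df = df.assign(_abs_lfc=df["logFC"].abs()).sort_values(
        ["q", "_abs_lfc"], ascending=[True, False]
    )
    best = df.groupby("gene_id", sort=True).first()
    sig = df.groupby("gene_id", sort=True)["significant"].any()
    return pd.DataFrame(
        {"significant": sig, "direction": best["direction"], "best_q": best["q"]}
    )


@dataclass
class CasiBiasResult:
    applicable: bool
    statistic: float = np.nan
    p: float = np.nan
    n_genes: int = 0
    n_probesets: int = 0
    B: int = 0
    null_mean: float = np.nan
    verdict: str = "not applicable"
    flagged_bias: bool = False
    notes: list[str] = field(default_factory=list)


def _replicate_spread(expression: pd.DataFrame, samples: pd.DataFrame, idx) -> np.ndarray:
    """Per-probe-set mean absolute inter-replicate log-ratio across tissues."""
    sub = expression.loc[idx]
    spreads = []
    for tissue in dict.fromkeys(samples["tissue"]):
        cols = samples.index[samples["tissue"] == tissue]
        vals = sub[cols].values
        n = vals.shape[1]
        if n < 2:
            continue
        pair_sum = np.zeros(vals.shape[0])
        n_pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                pair_sum += np.abs(vals[:, i] - vals[:, j])
                n_pairs += 1
        spreads.append(pair_sum / n_pairs)
    return np.mean(spreads, axis=0)


def casi_bias_check(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    casi_genes,
    annotation: pd.Series,
    B: int = 1000,
    seed: int = 0,
) -> CasiBiasResult:
    """Screen pooled replicates for sex-linked expression bias.

    Statistic: mean absolute inter-replicate log2 ratio over CASI-gene
    probe-sets (pooling across embryos should average sex out; a residual
    replicate-linked shift in sex-identity genes inflates this spread).
    The null redraws B random probe-set groups of equal size; empirical
    p = (b + 1)/(B + 1).
    """
    casi_set = set(casi_genes)
    if not casi_set:
        return CasiBiasResult(applicable=False, notes=["empty CASI list"])
    mapped = annotation[annotation.isin(casi_set)]
    ps = [p for p in mapped.index if p in expression.index]
    if not ps:
        return CasiBiasResult(applicable=False, notes=["no CASI genes mapped to the array"])

    observed = float(_replicate_spread(expression, samples, ps).mean())
    rng = np.random.default_rng(seed)
    all_ps = np.array(expression.index)
    exceed = 0
    for _ in range(B):
        draw = rng.choice(all_ps, size=len(ps), replace=False)
        if float(_replicate_spread(expression, samples, draw).mean()) >= observed:
            exceed += 1
    p = (exceed + 1) / (B + 1)
    flagged = p < 0.05
    return CasiBiasResult(
        applicable=True,
        statistic=observed,
        p=p,
        n_genes=len(set(mapped)),
        n_probesets=len(ps),
        B=B,
        verdict="sex-linked bias flagged" if flagged else "no strong sex-linked bias",
        flagged_bias=flagged,
    )
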