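"""Cell-cycle kinetics from dual-exposure cumulative EdU labeling.

Under cumulative labeling all cycling cells outside S phase enter it at a
constant rate, so the labeled fraction grows linearly with exposure time:

    L(t) = (S + t) / T        (valid while L < 1)

with T the total cycle time and S the S-phase length (hours).  Two exposure
times give two simultaneous equations; subtracting them yields
T = (t2 - t1)/(L2 - L1) and substituting T back gives S = L1*T - t1.  The
model assumes all cells are cycling (no growth-fraction or death
correction).  Mitotic index is the phospho-histone-H3-positive fraction of
nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def transition_window_hours(n_somites: int = 3, somite_period_h: float = 1.5) -> float:
    """Time span of the switch region: somite lengths × somite formation
    period (3 × 1.5 h = 4.5 h by default)."""
    if n_somites <= 0 or somite_period_h <= 0:
        raise ValueError("somite count and period must be positive")
    return n_somites * somite_period_h


@dataclass
class CellCycleEstimate:
    region: str
    T: float  # total cycle time, hours
    S: float  # S-phase length, hours
    S_fraction: float
    se_T: float
    se_S: float
    se_S_fraction: float
    n_embryos: int
    flagged: bool = False  # S <= 0 or other suspect geometry
    notes: str = ""


def _pooled_fractions(obs: pd.DataFrame) -> pd.Series:
    """Count-weighted labeled fraction per exposure time."""
    grouped = obs.groupby("exposure_h")
    return grouped["edu_pos"].sum() / grouped["total"].sum()


def _invert(times: np.ndarray, fractions: np.ndarray) -> tuple[float, float]:
    """Solve the simultaneous labeling equations.

    With two exposure times this is the subtraction estimator exactly; with
    more, the least-squares line through (t, L) generalizes it (the two-point
    case reduces to the same formula).
    """
    if len(times) == 2:
        (t1, t2), (l1, l2) = times, fractions
        dL = l2 - l1
        if dL <= 0:
            raise ValueError("labeling not increasing between exposure times")
        T = (t2 - t1) / dL
        S = l1 * T - t1
    else:
        slope, intercept = np.polyfit(times, fractions, 1)
        if slope <= 0:
            raise ValueError("labeling not increasing between exposure times")
        T = 1.0 / slope
        S = intercept * T
    return float(T), float(S)


def estimate_cell_cycle(obs: pd.DataFrame, region: str | None = None) -> CellCycleEstimate:
    """Estimate (T, S) for one region; SE by leave-one-embryo-out jackknife.

    ``obs`` columns: region, embryo, section, exposure_h, edu_pos, total.
    Labeled fractions are pooled count-weighted within each exposure time.
    """
    if region is not None:
        obs = obs[obs["region"] == region]
    regions = sorted(set(obs["region"])) if "region" in obs.columns else ["?"]
    if len(regions) != 1:
        raise ValueError(f"observations span several regions {regions}; pass region=")
    if (obs["edu_pos"] > obs["total"]).any() or (obs["edu_pos"] < 0).any():
        raise ValueError("EdU counts must satisfy 0 <= edu_pos <= total")
    times = np.array(sorted(set(obs["exposure_h"])), dtype=float)
    if len(times) < 2:
        raise ValueError("need observations at >= 2 distinct exposure times")

    fractions = _pooled_fractions(obs).reindex(times).values
    T, S = _invert(times, fractions)
    flagged = not (0 < S < T)

    embryos = sorted(set(obs["embryo"]))
    jack = []
    for e in embryos:
        sub = obs[obs["embryo"] != e]
        try:
            fr = _pooled_fractions(sub).reindex(times).values
            Ti, Si = _invert(times, fr)
            jack.append((Ti, Si, Si / Ti))
        except ValueError:
            jack.append((np.nan, np.nan, np.nan))
    jack_arr = np.array(jack, dtype=float)
    n = len(embryos)
    if n >= 2 and not np.isnan(jack_arr).any():
        se = np.sqrt((n - 1) / n * ((jack_arr - jack_arr.mean(axis=0)) ** 2).sum(axis=0))
    else:
        se = np.array([np.nan, np.nan, np.nan])

    return CellCycleEstimate(
        region=regions[0],
        T=T,
        S=S,
        S_fraction=S / T,
        se_T=float(se[0]),
        se_S=float(se[1]),
        se_S_fraction=float(se[2]),
        n_embryos=n,
        flagged=flagged,
        notes="S outside (0, T)" if flagged else "",
    )


def estimate_per_embryo(obs: pd.DataFrame, metric_extra: bool = True) -> pd.DataFrame:
    """Per-embryo (T, S, S_fraction) estimates for between-region testing."""
    rows = []
    for (region, embryo), sub in obs.groupby(["region", "embryo"]):
        times = np.array(sorted(set(sub["exposure_h"])), dtype=float)
        if len(times) < 2:
            continue
        try:
            T, S = _invert(times, _pooled_fractions(sub).reindex(times).values)
        except ValueError:
            continue
        rows.append(
            {"region": region, "embryo": embryo, "T": T, "S": S, "S_fraction": S / T}
        )
    return pd.DataFrame(rows)


def mitotic_index(counts: pd.DataFrame, by=("region",)) -> pd.DataFrame:
    """Phospho-H3-positive fraction of nuclei, pooled count-weighted.

    Pass ``by=("region", "embryo")`` to retain per-embryo values for
    statistical comparison.
    """
    if "ph3_pos" not in counts.columns:
        raise ValueError("counts table lacks a ph3_pos column")
    if (counts["total"] <= 0).any():
        raise ValueError("total nuclei counts must be positive")
    grouped = counts.groupby(list(by))
    out = grouped[["ph3_pos", "total"]].sum()
    out["index"] = out["ph3_pos"] / out["total"]
    return out.reset_index()


def compare_regions(
    per_embryo: pd.DataFrame, metric: str = "T", welch: bool = True
) -> pd.DataFrame:
    """Pairwise two-sided t-tests of a per-embryo metric between regions.

    Welch's unequal-variance t by default; ``welch=False`` gives the
    pooled-variance Student test.
    """
    if metric not in per_embryo.columns:
        raise ValueError(f"metric {metric!r} not in table")
    regions = sorted(set(per_embryo["region"]))
    rows = []
    for ra, rb in combinations(regions, 2):
        xa = per_embryo.loc[per_embryo["region"] == ra, metric].values
        xb = per_embryo.loc[per_embryo["region"] == rb, metric].values
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"need >= 2 embryos per region ({ra} vs {rb})")
        if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]) and np.isclose(xa[0], xb[0]):
            t, p = 0.0, 1.0  # identical degenerate samples
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
        rows.append(
            {"region_a": ra, "region_b": rb, "metric": metric,
             "mean_a": xa.mean(), "mean_b": xb.mean(), "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows)
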