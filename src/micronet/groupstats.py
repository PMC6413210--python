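"""Two-group differential abundance, tumor volume, and growth-curve
fitting/comparison.

The rank-sum test is exact (full enumeration of group assignments) for
small tie-free samples and otherwise uses the normal approximation with
midranks, tie correction, and continuity correction. Multiple testing is
controlled by Benjamini-Hochberg FDR. Tumor volume uses the ellipsoid
approximation V = 0.523 * L * W^2 (cm^3); growth curves are single-phase
exponentials V(t) = V0 * exp(k t) compared by the extra-sum-of-squares
F test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import OtuTable

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # enumerate all C(n, nx) splits up to this total size


def _rankdata_mid(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank-sum statistic of ``x`` using midranks, two-sided p).
    Exact by enumeration when n_x + n_y <= 12 and there are no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    ranks = _rankdata_mid(pooled)
    w = float(ranks[:nx].sum())
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_MAX_N and not has_ties:
        # exact null: rank-sum over all C(n, nx) assignments
        all_ranks = np.arange(1, n + 1)
        sums = np.fromiter((sum(c) for c in combinations(all_ranks, nx)),
                           dtype=float, count=math.comb(n, nx))
        mean = nx * (n + 1) / 2.0
        dev = abs(w - mean)
        p = float(np.mean(np.abs(sums - mean) >= dev - 1e-9))
        return w, min(p, 1.0)

    mean = nx * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n) * (n - 1))
    var = nx * y.size / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(2.0 * stats.norm.sf(z))
    return w, min(p, 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforced."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class DiffAbundanceRecord:
    otu_id: str
    mean_control: float
    sd_control: float
    mean_treatment: float
    sd_treatment: float
    statistic: float
    p: float
    q: float
    fold_change: float          # treatment mean / control mean; nan when undefined
    direction: str              # "up" (higher in treatment), "down", or "none"
    lineage: str = ""


def fold_change(mean_treatment: float, mean_control: float) -> float:
    """Treatment/control ratio of group mean percent abundances; NaN when
    the control mean is zero (flagged undefined)."""
    if mean_control == 0:
        return float("nan")
    return mean_treatment / mean_control


def differential_abundance(table: OtuTable, group_labels: list[str],
                           control_group: str | None = None,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-OTU two-group comparison on percent relative abundance.

    For every OTU: group mean +/- sd of percent composition, rank-sum p,
    BH q, and fold change (treatment mean / control mean). Records are
    sorted by q then p. ``control_group`` defaults to the lexicographically
    first label.
    """
    labels = np.asarray([str(g) for g in group_labels])
    if labels.size != table.n_samples:
        raise ValueError("one group label required per sample")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    ctrl = control_group if control_group is not None else groups[0]
    if ctrl not in groups:
        raise ValueError(f"unknown control group {ctrl!r}")
    treat = [g for g in groups if g != ctrl][0]
    ctrl_mask = labels == ctrl
    if ctrl_mask.sum() < 3 or (~ctrl_mask).sum() < 3:
        raise ValueError("each group needs at least 3 samples")

    totals = table.counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a sample has zero total count")
    pct = 100.0 * table.counts / totals

    recs = []
    for i, oid in enumerate(table.otu_ids):
        xc = pct[i, ctrl_mask]
        xt = pct[i, ~ctrl_mask]
        stat, p = wilcoxon_rank_sum(xt, xc)
        mc, mt = float(xc.mean()), float(xt.mean())
        recs.append(DiffAbundanceRecord(
            otu_id=oid, mean_control=mc, sd_control=float(xc.std(ddof=1)),
            mean_treatment=mt, sd_treatment=float(xt.std(ddof=1)),
            statistic=stat, p=p, q=np.nan, fold_change=fold_change(mt, mc),
            direction="up" if mt > mc else ("down" if mt < mc else "none"),
            lineage=table.lineages[i]))
    q = bh_adjust(np.array([r.p for r in recs]))
    for r, qv in zip(recs, q):
        r.q = float(qv)
    df = pd.DataFrame([r.__dict__ for r in recs])
    df["significant"] = df["q"] < alpha
    return df.sort_values(["q", "p", "otu_id"], kind="stable").reset_index(drop=True)


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid tumor volume in cm^3: 0.523 * length * width^2.

    Length is by convention the larger calliper axis; swapped (with a
    warning) if given the other way round.
    """
    if length < 0 or width < 0:
        raise ValueError("calliper measurements must be non-negative")
    if width > length:
        logger.warning("width %.3g > length %.3g; swapping axes", width, length)
        length, width = width, length
    return 0.523 * length * width ** 2


def fit_growth_curve(times: np.ndarray, volumes: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of V(t) = V0 * exp(k t).

    Returns (V0, k, residual sum of squares). The nonlinear fit is
    initialized from the log-linear regression of ln V on t.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    slope, intercept = np.polyfit(t, np.log(v), 1)
    p0 = (math.exp(intercept), slope)
    popt, _ = optimize.curve_fit(lambda tt, v0, k: v0 * np.exp(k * tt), t, v,
                                 p0=p0, maxfev=10_000)
    v0, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((v - v0 * np.exp(k * t)) ** 2))
    return v0, k, rss


def compare_growth_curves(times_a: np.ndarray, volumes_a: np.ndarray,
                          times_b: np.ndarray, volumes_b: np.ndarray
                          ) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares F test: one shared exponential curve for both
    groups vs a separate curve per group.

    Returns (F, df_numerator, df_denominator, p).
    """
    ta, va = np.asarray(times_a, float), np.asarray(volumes_a, float)
    tb, vb = np.asarray(times_b, float), np.asarray(volumes_b, float)
    _, _, rss_a = fit_growth_curve(ta, va)
    _, _, rss_b = fit_growth_curve(tb, vb)
    _, _, rss_shared = fit_growth_curve(np.concatenate([ta, tb]),
                                        np.concatenate([va, vb]))
    rss_sep = rss_a + rss_b
    n = ta.size + tb.size
    df_sep = n - 4    # two parameters per group
    df_num = 2        # extra parameters of the separate model
    if df_sep <= 0:
        raise ValueError("not enough data points to compare fits")
    if rss_sep <= 0:
        # perfect separate fits: infinitely strong evidence unless shared also perfect
        return (0.0, df_num, df_sep, 1.0) if rss_shared <= 1e-300 else \
            (float("inf"), df_num, df_sep, 0.0)
    f = max(((rss_shared - rss_sep) / df_num) / (rss_sep / df_sep), 0.0)
    p = float(stats.f.sf(f, df_num, df_sep))
    return float(f), df_num, df_sep, p
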