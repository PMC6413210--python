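"""Similarity matrix construction and random-matrix-theory threshold selection.

The threshold at which a correlation network stops being noise-dominated is
found by scanning cutoffs and testing, at each one, the nearest-neighbour
spacing distribution (NNSD) of the thresholded matrix's unfolded eigenvalues.
A noise-dominated (dense, random) matrix follows the Gaussian orthogonal
ensemble (GOE, Wigner surmise); once only real modular structure survives,
the spectrum fragments into near-independent blocks and the spacings become
Poisson. The selected threshold s* is the smallest cutoff whose NNSD is
statistically indistinguishable from Poisson.

Unfolding maps eigenvalues through a smooth monotone fit of the cumulative
spectral function so that spacings have unit mean; here a monotone (PCHIP)
cubic through a decimated set of knots of the empirical staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson correlations of OTU abundance profiles.

    ``magnitude`` (|r|) drives thresholding; ``signed`` keeps the sign for
    edge annotation (cooperative vs competitive association).
    """

    otu_ids: list[str]
    signed: np.ndarray

    def __post_init__(self) -> None:
        self.signed = np.asarray(self.signed, dtype=float)
        n = len(self.otu_ids)
        if self.signed.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.signed, self.signed.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.signed), 1.0, atol=1e-12):
            raise ValueError("similarity matrix must have unit diagonal")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.signed)


@dataclass
class RmtScanResult:
    """Per-threshold NNSD test records and the selected threshold."""

    scan: pd.DataFrame            # threshold, n_nodes, n_edges, n_eigenvalues,
                                  # chi2_poisson, p_poisson, chi2_goe
    threshold: float              # selected s*
    alpha: float

    def record_at(self, s: float) -> pd.Series:
        idx = (self.scan["threshold"] - s).abs().idxmin()
        return self.scan.loc[idx]


def pearson_similarity(abund) -> SimilarityMatrix:
    """Pairwise Pearson correlation of OTU profiles across samples.

    Zero-variance OTU rows are rejected (filter them out first).
    """
    x = np.asarray(abund.values, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance OTU {abund.otu_ids[dead[0]]!r}; apply a prevalence/variance filter first")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(list(abund.otu_ids), r)


def spectral_unfold(eigenvalues: np.ndarray, smoothing: int = 11,
                    degeneracy_tol: float = 1e-8) -> np.ndarray:
    """Unfold a sorted spectrum to unit-mean nearest-neighbour spacings.

    Duplicate eigenvalues (within ``degeneracy_tol``) are removed, the
    empirical cumulative spectral function is fit with a monotone cubic
    through ``smoothing`` knots, and spacings of the mapped eigenvalues are
    returned.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    # degeneracy removal: collapse runs closer than tol
    keep = np.ones(lam.size, dtype=bool)
    keep[1:] = np.diff(lam) > degeneracy_tol
    lam = lam[keep]
    n = lam.size
    if n < 20:
        raise ValueError(f"need >= 20 distinct eigenvalues to unfold, got {n}")
    cum = np.arange(1, n + 1, dtype=float)
    n_knots = int(np.clip(smoothing, 4, n))
    knot_idx = np.unique(np.linspace(0, n - 1, n_knots).round().astype(int))
    # guard against coincident knot abscissae
    knots_x, uniq = np.unique(lam[knot_idx], return_index=True)
    knots_y = cum[knot_idx][uniq]
    fit = PchipInterpolator(knots_x, knots_y, extrapolate=True)
    unfolded = fit(lam)
    spacings = np.diff(unfolded)
    return spacings


def _nnsd_expected(law: str, edges: np.ndarray) -> np.ndarray:
    """Bin probabilities of the reference spacing law on [edges]."""
    if law == "poisson":
        cdf = 1.0 - np.exp(-edges)
    elif law == "goe":
        # Wigner surmise P(d) = (pi d / 2) exp(-pi d^2 / 4)
        cdf = 1.0 - np.exp(-np.pi * edges ** 2 / 4.0)
    else:
        raise ValueError(f"unknown law {law!r}; expected 'poisson' or 'goe'")
    p = np.diff(cdf)
    p[-1] += 1.0 - cdf[-1]  # pool the tail beyond the last edge
    return p


def nnsd_chi_square(spacings: np.ndarray, law: str = "poisson",
                    bin_width: float = 0.1, d_max: float = 3.0) -> tuple[float, float]:
    """Chi-square goodness of fit of the NNSD against Poisson or GOE.

    Spacings are histogrammed with ``bin_width`` on [0, d_max] with the tail
    pooled into the last bin; adjacent bins are further pooled until every
    expected count is >= 5, and the statistic is referred to chi-square with
    (pooled bins - 1) degrees of freedom.
    """
    d = np.asarray(spacings, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 20:
        raise ValueError(f"need >= 20 spacings, got {d.size}")
    # the reference laws describe unit-mean spacings; compare shape only
    mean = d.mean()
    if mean <= 0:
        raise ValueError("spacings must have a positive mean")
    d = d / mean
    edges = np.arange(0.0, d_max + bin_width / 2, bin_width)
    obs, _ = np.histogram(np.clip(d, 0.0, d_max - bin_width / 2), bins=edges)
    exp_p = _nnsd_expected(law, edges)
    exp = exp_p * d.size

    # Cochran pooling: merge adjacent bins until each expected count >= 5
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5.0:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if pooled_exp:
            pooled_obs[-1] += acc_o
            pooled_exp[-1] += acc_e
        else:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
    pooled_obs = np.asarray(pooled_obs, dtype=float)
    pooled_exp = np.asarray(pooled_exp, dtype=float)
    if pooled_obs.size < 2:
        raise ValueError("too few occupied histogram bins for a chi-square test")
    chi2 = float(np.sum((pooled_obs - pooled_exp) ** 2 / pooled_exp))
    dof = pooled_obs.size - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p


def _thresholded_spectrum(mag: np.ndarray, s: float) -> tuple[int, int, np.ndarray]:
    """Apply |r| >= s off the diagonal, drop isolated nodes, and return
    (n_nodes, n_edges, eigenvalues of the surviving submatrix)."""
    a = mag.copy()
    np.fill_diagonal(a, 0.0)
    a[a < s] = 0.0
    deg = (a > 0).sum(axis=1)
    keep = deg > 0
    n_nodes = int(keep.sum())
    n_edges = int((a[np.ix_(keep, keep)] > 0).sum() // 2)
    if n_nodes == 0:
        return 0, 0, np.empty(0)
    sub = a[np.ix_(keep, keep)]
    np.fill_diagonal(sub, 1.0)
    lam = np.linalg.eigvalsh(sub)
    return n_nodes, n_edges, lam


def rmt_threshold_scan(sim: SimilarityMatrix, s_min: float = 0.30, s_max: float = 0.99,
                       step: float = 0.01, alpha: float = 0.05, min_nodes: int = 30,
                       smoothing: int = 11) -> RmtScanResult:
    """Scan correlation cutoffs and select the RMT threshold s*.

    At each cutoff the surviving matrix is eigendecomposed, unfolded, and
    its NNSD tested against Poisson; s* is the smallest scanned cutoff whose
    Poisson chi-square p-value is >= ``alpha`` while the surviving network
    still has >= ``min_nodes`` nodes. The full scan table is always
    returned (and attached to the error when no cutoff qualifies).
    """
    mag = sim.magnitude
    thresholds = np.round(np.arange(s_min, s_max + step / 2, step), 10)
    records = []
    for s in thresholds:
        n_nodes, n_edges, lam = _thresholded_spectrum(mag, s)
        rec = {"threshold": float(s), "n_nodes": n_nodes, "n_edges": n_edges,
               "n_eigenvalues": np.nan, "chi2_poisson": np.nan,
               "p_poisson": np.nan, "chi2_goe": np.nan}
        if n_nodes >= 2 and lam.size:
            try:
                spacings = spectral_unfold(lam, smoothing=smoothing)
                rec["n_eigenvalues"] = spacings.size + 1
                chi2_p, p_p = nnsd_chi_square(spacings, "poisson")
                chi2_g, _ = nnsd_chi_square(spacings, "goe")
                rec.update(chi2_poisson=chi2_p, p_poisson=p_p, chi2_goe=chi2_g)
            except ValueError:
                pass  # too few eigenvalues/spacings at this cutoff
        records.append(rec)
    scan = pd.DataFrame.from_records(records)
    ok = scan[(scan["p_poisson"] >= alpha) & (scan["n_nodes"] >= min_nodes)]
    if ok.empty:
        err = ValueError(
            "no scanned threshold passed the Poisson NNSD criterion with "
            f">= {min_nodes} surviving nodes")
        err.scan = scan  # type: ignore[attr-defined]
        raise err
    s_star = float(ok["threshold"].iloc[0])
    return RmtScanResult(scan=scan, threshold=s_star, alpha=alpha)
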