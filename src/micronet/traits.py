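"""Module eigengenes, module-trait correlation, OTU significance, and the
Mantel test linking network topology to a host trait.

A module eigengene is the first principal component of the module members'
standardized abundance profiles, scaled to unit variance and oriented so
that its mean correlation with the member profiles is non-negative — one
representative value per sample for the whole module. OTU significance is
the squared correlation of an OTU's abundance profile with the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ModuleTraitResult:
    """One module's eigengene and its association with the trait."""

    module: int
    size: int
    eigengene: np.ndarray
    variance_explained: float
    r: float = np.nan
    p: float = np.nan


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant profile in module; filter zero-variance members first")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def module_eigengene(abund, members: list[str]) -> tuple[np.ndarray, float]:
    """First principal component of the standardized member profiles.

    Returns (eigengene scaled to unit variance, share of variance explained
    by the leading component). Orientation: flipped so the mean correlation
    with member profiles is >= 0; an exact tie is broken toward the sign of
    the lexicographically first member's loading.
    """
    idx = {o: i for i, o in enumerate(abund.otu_ids)}
    missing = [m for m in members if m not in idx]
    if missing:
        raise KeyError(f"members missing from abundance matrix: {missing[:5]}")
    if len(members) < 2:
        raise ValueError("a module eigengene needs at least 2 members")
    x = np.asarray(abund.values, dtype=float)[[idx[m] for m in members], :]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    z = _zscore_rows(x)
    # SVD of members x samples; right singular vector = sample scores
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0, :]
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    eig = scores / scores.std()
    mean_corr = float(np.mean([np.corrcoef(eig, row)[0, 1] for row in z]))
    first = min(range(len(members)), key=lambda i: members[i])
    if mean_corr < 0 or (mean_corr == 0 and np.corrcoef(eig, z[first])[0, 1] < 0):
        eig = -eig
    return eig, var_explained


def module_trait_correlation(abund, partition, trait: np.ndarray,
                             min_size: int = 2) -> list[ModuleTraitResult]:
    """Pearson correlation of each module eigengene with the trait.

    p-values come from the t-transform t = r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom, two-tailed.
    """
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if n != len(abund.sample_ids):
        raise ValueError("trait length does not match sample count")
    if n < 4:
        raise ValueError("need at least 4 samples for a trait correlation")
    results = []
    for m in sorted(set(partition.labels.values())):
        members = sorted(partition.members(m))
        members = [x for x in members if x in set(abund.otu_ids)]
        if len(members) < min_size:
            continue
        eig, ve = module_eigengene(abund, members)
        r, p = pearson_with_t_pvalue(eig, trait)
        results.append(ModuleTraitResult(module=m, size=len(members), eigengene=eig,
                                         variance_explained=ve, r=r, p=p))
    return results


def pearson_with_t_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-tailed t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def otu_significance(abund, trait: np.ndarray) -> pd.Series:
    """Squared Pearson correlation of each OTU profile with the trait.

    Zero-variance profiles get significance 0 with a logged warning.
    """
    trait = np.asarray(trait, dtype=float)
    x = np.asarray(abund.values, dtype=float)
    if trait.size != x.shape[1]:
        raise ValueError("trait length does not match sample count")
    out = np.zeros(x.shape[0])
    sd = x.std(axis=1)
    tc = trait - trait.mean()
    t_norm = np.linalg.norm(tc)
    for i in range(x.shape[0]):
        if sd[i] == 0 or t_norm == 0:
            if sd[i] == 0:
                logger.warning("zero-variance OTU %s: significance set to 0",
                               abund.otu_ids[i])
            continue
        xc = x[i] - x[i].mean()
        r = float(xc @ tc / (np.linalg.norm(xc) * t_norm))
        out[i] = r * r
    return pd.Series(out, index=abund.otu_ids, name="otu_significance")


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def mantel_test(d1: np.ndarray, d2: np.ndarray, n_perm: int = 999,
                seed: int = 0) -> MantelResult:
    """Mantel test: Pearson correlation of the lower triangles of two
    distance matrices, with a one-tailed permutation p-value obtained by
    jointly permuting rows and columns of the second matrix.

    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    d1 = _check_distance_matrix(d1, "D1")
    d2 = _check_distance_matrix(d2, "D2")
    n = d1.shape[0]
    if d2.shape[0] != n:
        raise ValueError("distance matrices must have the same order")
    if n < 4:
        raise ValueError("need at least 4 objects for a Mantel test")
    tri = np.tril_indices(n, k=-1)
    v1 = d1[tri]
    v1c = v1 - v1.mean()
    n1 = np.linalg.norm(v1c)

    def corr_with(mat: np.ndarray) -> float:
        v2 = mat[tri]
        v2c = v2 - v2.mean()
        n2 = np.linalg.norm(v2c)
        if n1 == 0 or n2 == 0:
            raise ValueError("constant distance matrix")
        return float(v1c @ v2c / (n1 * n2))

    r_obs = corr_with(d2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(d2[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)


def connectivity_trait_mantel(net, abund, trait: np.ndarray, n_perm: int = 999,
                              seed: int = 0) -> MantelResult:
    """Topology-trait link: Mantel test between pairwise |difference| of OTU
    significances and pairwise |difference| of node degree, over network
    nodes present in the abundance matrix."""
    sig = otu_significance(abund, trait)
    nodes = sorted(n for n in net.nodes if n in sig.index)
    if len(nodes) < 4:
        raise ValueError("need at least 4 network nodes with abundance profiles")
    s = sig[nodes].to_numpy()
    k = np.array([net.degree[n] for n in nodes], dtype=float)
    d1 = np.abs(s[:, None] - s[None, :])
    d2 = np.abs(k[:, None] - k[None, :])
    return mantel_test(d1, d2, n_perm=n_perm, seed=seed)
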