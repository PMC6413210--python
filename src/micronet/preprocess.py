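"""Prevalence filtering, abundance transforms, taxonomic aggregation, and
alpha-diversity / rarefaction summaries.

Chao1 (bias-corrected), Shannon (natural log by default), and Simpson
(1 - sum p^2) are computed through scikit-bio's alpha-diversity routines.
Rarefaction uses the analytic hypergeometric expectation rather than
repeated subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio.diversity.alpha import chao1, shannon, simpson

from .io import OtuTable, parse_lineage, RANKS


@dataclass
class AbundanceMatrix:
    """Relative abundances (OTUs x samples); ``log_transformed`` flags the
    provenance of the values."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("abundance shape mismatch")
        if not self.log_transformed:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("untransformed abundance columns must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)


def prevalence_filter(table: OtuTable, min_fraction: float = 0.5) -> OtuTable:
    """Drop OTUs detected (count > 0) in fewer than ``min_fraction`` of samples.

    The boundary is inclusive: an OTU present in exactly ``min_fraction`` of
    samples is retained. Row order is preserved.
    """
    if table.n_otus == 0 or table.n_samples == 0:
        raise ValueError("empty OTU table")
    frac = (table.counts > 0).sum(axis=1) / table.n_samples
    keep = np.flatnonzero(frac >= min_fraction)
    if keep.size == 0:
        raise ValueError(
            f"prevalence filter at {min_fraction:.0%} removed every OTU; lower the threshold")
    return table.select_otus(keep)


def relative_abundance(table: OtuTable) -> AbundanceMatrix:
    """Divide each sample column by its total count."""
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    return AbundanceMatrix(list(table.otu_ids), list(table.sample_ids),
                           table.counts / totals)


def log_transform(abund: AbundanceMatrix, pseudocount: float = 1e-6) -> AbundanceMatrix:
    """Elementwise log10(abundance + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if abund.log_transformed:
        raise ValueError("abundance matrix is already log-transformed")
    return AbundanceMatrix(list(abund.otu_ids), list(abund.sample_ids),
                           np.log10(abund.values + pseudocount), log_transformed=True)


def aggregate_by_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts over OTUs sharing the named taxonomy rank.

    OTUs whose lineage has no assignment at ``rank`` are pooled as
    ``"Unassigned"``. Output rows are sorted by descending total count.
    """
    rank = rank.lower()
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    taxa = []
    for lin in table.lineages:
        name = parse_lineage(lin).rank(rank)
        taxa.append(name if name else "Unassigned")
    df = table.to_frame()
    df.index = pd.Index(taxa, name=rank)
    agg = df.groupby(level=0).sum()
    agg = agg.loc[agg.sum(axis=1).sort_values(ascending=False, kind="stable").index]
    return OtuTable(list(agg.index), list(table.sample_ids),
                    agg.to_numpy(dtype=np.int64))


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed richness, bias-corrected Chao1, Shannon entropy
    (nats), and Simpson index (1 - sum p^2)."""
    totals = table.counts.sum(axis=0)
    if np.any(totals == 0):
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total count")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j].astype(np.int64)
        rows.append({
            "sample_id": sid,
            "observed": int((col > 0).sum()),
            "chao1": float(chao1(col, bias_corrected=True)),
            "shannon": float(shannon(col, base=np.e)),
            "simpson": float(simpson(col)),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def rarefaction_curve(sample_counts: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Analytic expected richness at each subsampling depth (without
    replacement): E[S_d] = sum_i [1 - C(N - N_i, d) / C(N, d)].
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    counts = counts[counts > 0]
    depths = np.asarray(depths, dtype=np.int64)
    n_total = int(counts.sum())
    if np.any(depths < 1) or np.any(np.diff(depths) <= 0) and depths.size > 1:
        raise ValueError("depths must be increasing positive integers")
    if np.any(depths > n_total):
        raise ValueError(f"depth exceeds sample total {n_total}")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(depths.size, dtype=float)
    for idx, d in enumerate(depths):
        rest = n_total - counts  # reads not belonging to taxon i
        with np.errstate(invalid="ignore"):
            log_p_absent = np.where(rest >= d,
                                    log_comb(rest, d) - log_comb(n_total, d),
                                    -np.inf)
        out[idx] = float(np.sum(1.0 - np.exp(log_p_absent)))
    return out
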