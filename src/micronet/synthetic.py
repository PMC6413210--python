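"""Synthetic community generator with planted co-occurrence modules.

The generator emulates a 16S amplicon experiment at desk scale: blocks of
co-varying OTUs driven by shared latent factors, a compositional count
layer (multinomial at fixed sequencing depth), prevalence dropout, and a
host trait coupled to one chosen module. It also produces weekly tumor
calliper series consistent with the volume formula 0.523*L*W^2.

Log-scale abundance model, per OTU i and sample j::

    x_ij = mu_i + lambda * f_{m(i), j} + eps_ij

with module factors f ~ N(0, 1) drawn per (module, sample), OTU baselines
mu_i ~ N(0, 1), and noise eps ~ N(0, sigma^2). Background OTUs have no
factor term. Counts are a multinomial draw of softmax(x_.j) at the stated
depth. The trait is ``beta * f_{m*, j} + N(0, 1)`` for the linked module
m*, so its correlation with the latent factor tends to beta/sqrt(beta^2+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import OtuTable, TraitTable

# round-robin phylum pool, loosely matching common murine gut taxa
_PHYLA = ("Firmicutes", "Bacteroidetes", "Deferribacteres",
          "Proteobacteria", "Actinobacteria", "Verrucomicrobia")


@dataclass
class SyntheticParams:
    """Knobs of the community generator.

    Defaults mirror the emulated study design: 9 samples per group,
    ~767 OTUs in total, and one trait-linked module.
    """

    n_samples: int = 9
    module_sizes: tuple[int, ...] = (30, 25, 20, 15, 12, 10, 8, 7)
    n_background: int = 640
    loading: float = 1.5          # lambda: factor loading within modules
    noise_sd: float = 0.5         # sigma: log-scale residual noise
    depth: int = 50_000           # reads per sample
    dropout: float = 0.05         # per-cell post-sampling zeroing probability
    trait_coupling: float = 1.5   # beta
    trait_module: int = 0         # index of the trait-linked module
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not self.module_sizes:
            raise ValueError("at least one module is required")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be a probability in [0, 1)")
        if self.noise_sd < 0:
            # sigma = 0 is permitted as the documented noise-free limit
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.trait_module < len(self.module_sizes):
            raise ValueError("trait_module must index an existing module")

    @property
    def n_otus(self) -> int:
        return int(sum(self.module_sizes) + self.n_background)


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream validation."""

    module_of: np.ndarray          # int label per OTU; -1 = background
    factors: np.ndarray            # (n_modules, n_samples) latent factors
    trait: np.ndarray = field(default=None)  # type: ignore[assignment]


def generate_community(params: SyntheticParams) -> tuple[OtuTable, TraitTable, GroundTruth]:
    """Draw one synthetic community; fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n_mod = len(params.module_sizes)
    n_otus, n_samples = params.n_otus, params.n_samples

    module_of = np.full(n_otus, -1, dtype=int)
    pos = 0
    for m, size in enumerate(params.module_sizes):
        module_of[pos:pos + size] = m
        pos += size

    mu = rng.normal(0.0, 1.0, size=n_otus)
    factors = rng.normal(0.0, 1.0, size=(n_mod, n_samples))
    eps = rng.normal(0.0, params.noise_sd, size=(n_otus, n_samples)) \
        if params.noise_sd > 0 else np.zeros((n_otus, n_samples))

    x = mu[:, None] + eps
    in_mod = module_of >= 0
    x[in_mod] += params.loading * factors[module_of[in_mod], :]

    # compositional count layer: multinomial of softmax(x) at fixed depth
    p = np.exp(x - x.max(axis=0, keepdims=True))
    p /= p.sum(axis=0, keepdims=True)
    counts = np.empty((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(params.depth, p[:, j])
    if params.dropout > 0:
        counts[rng.random(counts.shape) < params.dropout] = 0

    trait = params.trait_coupling * factors[params.trait_module, :] \
        + rng.normal(0.0, 1.0, size=n_samples)

    otu_ids = [f"OTU{i:04d}" for i in range(n_otus)]
    sample_ids = [f"S{j:02d}" for j in range(n_samples)]
    lineages = [
        f"k__Bacteria; p__{_PHYLA[i % len(_PHYLA)]}" for i in range(n_otus)
    ]
    table = OtuTable(otu_ids, sample_ids, counts, lineages)
    traits = TraitTable(sample_ids, trait)
    return table, traits, GroundTruth(module_of=module_of, factors=factors, trait=trait)


def _draw_group(params: SyntheticParams, mu: np.ndarray, module_of: np.ndarray,
                rng: np.random.Generator, log_offset: np.ndarray,
                sample_prefix: str, lineages: list[str]) -> tuple[OtuTable, TraitTable, GroundTruth]:
    """Counts/trait for one group given shared OTU baselines ``mu``."""
    n_otus, n_samples = mu.size, params.n_samples
    n_mod = len(params.module_sizes)
    factors = rng.normal(0.0, 1.0, size=(n_mod, n_samples))
    eps = rng.normal(0.0, params.noise_sd, size=(n_otus, n_samples)) \
        if params.noise_sd > 0 else np.zeros((n_otus, n_samples))
    x = mu[:, None] + eps + log_offset[:, None]
    in_mod = module_of >= 0
    x[in_mod] += params.loading * factors[module_of[in_mod], :]
    p = np.exp(x - x.max(axis=0, keepdims=True))
    p /= p.sum(axis=0, keepdims=True)
    counts = np.empty((n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(params.depth, p[:, j])
    if params.dropout > 0:
        counts[rng.random(counts.shape) < params.dropout] = 0
    trait = params.trait_coupling * factors[params.trait_module, :] \
        + rng.normal(0.0, 1.0, size=n_samples)
    otu_ids = [f"OTU{i:04d}" for i in range(n_otus)]
    sample_ids = [f"{sample_prefix}{j:02d}" for j in range(n_samples)]
    return (OtuTable(otu_ids, sample_ids, counts, list(lineages)),
            TraitTable(sample_ids, trait),
            GroundTruth(module_of=module_of, factors=factors, trait=trait))


def generate_two_group_community(params: SyntheticParams, shifted_module: int | None = None,
                                 shift: float = 2.0,
                                 shifted_baseline_offset: float = -2.5) -> dict:
    """Control and treatment communities with shared per-OTU baselines,
    mirroring a two-arm design: both groups draw from the same underlying
    community (same mu_i, same module memberships), with independent
    sample-level factors and noise.

    ``shifted_module`` OTUs get a log-abundance offset ``shift`` in the
    treatment group only. Their shared baseline is lowered by
    ``shifted_baseline_offset`` so the responding taxa are rare at baseline
    (a rare-taxon bloom); this keeps their total mass small, so the
    compositional renormalization does not spill a systematic shift onto
    every other taxon.
    """
    rng = np.random.default_rng(params.seed)
    n_otus = params.n_otus
    module_of = np.full(n_otus, -1, dtype=int)
    pos = 0
    for m, size in enumerate(params.module_sizes):
        module_of[pos:pos + size] = m
        pos += size
    mu = rng.normal(0.0, 1.0, size=n_otus)
    lineages = [f"k__Bacteria; p__{_PHYLA[i % len(_PHYLA)]}" for i in range(n_otus)]
    no_shift = np.zeros(n_otus)
    offset = np.zeros(n_otus)
    if shifted_module is not None:
        if not 0 <= shifted_module < len(params.module_sizes):
            raise ValueError("shifted_module must index an existing module")
        sel = module_of == shifted_module
        mu[sel] += shifted_baseline_offset
        offset[sel] = shift
    return {
        "control": _draw_group(params, mu, module_of, rng, no_shift, "S", lineages),
        "treatment": _draw_group(params, mu, module_of, rng, offset, "T", lineages),
    }


def generate_tumor_series(n_mice: int, weeks: int, v0: float, growth_rate: float,
                          noise_sd: float, seed: int = 0) -> "pd.DataFrame":
    """Weekly (length, width) calliper pairs per mouse, in cm.

    Volumes follow ``v0 * exp(growth_rate * t)`` plus additive Gaussian
    noise (cm^3, truncated below at a small positive value), then are
    back-converted to a calliper pair with width = 0.8 * length so that
    0.523 * L * W^2 reproduces the noisy volume.
    """
    import pandas as pd

    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if weeks < 2:
        raise ValueError("need at least 2 weekly measurements")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    t = np.arange(weeks, dtype=float)
    for mouse in range(n_mice):
        vol = v0 * np.exp(growth_rate * t)
        if noise_sd > 0:
            vol = np.maximum(vol + rng.normal(0.0, noise_sd, size=weeks), 1e-4)
        # V = 0.523 * L * (0.8 L)^2 = 0.523 * 0.64 * L^3
        length = (vol / (0.523 * 0.64)) ** (1.0 / 3.0)
        width = 0.8 * length
        for wk in range(weeks):
            rows.append({"mouse_id": f"m{mouse:02d}", "week": wk,
                         "length_cm": length[wk], "width_cm": width[wk],
                         "volume_cm3": vol[wk]})
    return pd.DataFrame(rows)
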