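# micronet

Microbial co-occurrence network analysis from OTU count tables: random-matrix
threshold selection, fast-greedy module separation, Zi/Pi node roles, and
module–trait association — with a synthetic community generator so the whole
pipeline is testable end to end without sequencing data.

## Who this is for

Microbiome researchers with a taxa × samples count table (16S OTU tables in
TSV or BIOM v1 JSON) and a per-sample host trait (e.g., tumor volume in cm³)
who want to ask: *which taxa co-vary as modules, and which module tracks the
host phenotype?* The package covers the desk-scale half of that workflow —
everything after OTU picking.

## The method

1. **Filter and transform.** OTUs detected in fewer than 50% of samples are
   excluded; counts become relative abundances, log₁₀-transformed with a
   pseudocount.
2. **Similarity.** Pairwise Pearson correlation r of abundance profiles
   across samples; thresholding acts on |r|, the sign is kept as edge
   annotation (cooperative `+` vs competitive `−`).
3. **RMT threshold.** For each candidate cutoff *s*, entries with |r| < s are
   zeroed and the surviving matrix is eigendecomposed. The nearest-neighbour
   spacing distribution (NNSD) of the unfolded eigenvalues follows the
   Gaussian orthogonal ensemble (Wigner surmise, P(d) = (πd/2)·e^(−πd²/4))
   while the matrix is noise-dominated, and Poisson (P(d) = e^(−d)) once only
   modular structure survives. The selected threshold s\* is the smallest
   cutoff whose NNSD is chi-square-compatible with Poisson.
4. **Modules.** Agglomerative fast-greedy maximization of modularity
   Q = Σₘ (e₍ₘₘ₎ − a₍ₘ₎²).
5. **Node roles.** Within-module degree z-score Zᵢ and participation
   coefficient Pᵢ = 1 − Σₜ (k₍ᵢₜ₎/kᵢ)², classified into peripheral /
   connector / module hub / network hub at the cutoffs Zᵢ = 2.5, Pᵢ = 0.62.
6. **Trait association.** Each module is summarized by its eigengene (first
   principal component of the members' standardized profiles, unit variance,
   oriented toward the members); Pearson r against the trait with a
   two-tailed t-distribution p. A Mantel permutation test relates per-OTU
   trait significance (squared correlation with the trait) to node
   connectivity.

Two-group comparisons (Wilcoxon rank-sum on percent composition, BH-FDR,
fold change) and tumor growth analysis (V = 0.523·L·W² cm³, exponential fits
compared by the extra-sum-of-squares F test) round out the toolbox.

## Worked example

```python
from micronet import (SyntheticParams, generate_community, prevalence_filter,
                      relative_abundance, log_transform, pearson_similarity,
                      rmt_threshold_scan, build_network, fast_greedy_modules,
                      network_summary)

params = SyntheticParams(n_samples=30, module_sizes=(20, 20, 20),
                         n_background=60, loading=1.5, noise_sd=0.5,
                         dropout=0.0, depth=20_000, seed=7)
table, traits, truth = generate_community(params)

abund = log_transform(relative_abundance(prevalence_filter(table, 0.5)))
sim = pearson_similarity(abund)
scan = rmt_threshold_scan(sim, min_nodes=30)
net = build_network(sim, scan.threshold)
part = fast_greedy_modules(net)
print(scan.threshold, network_summary(net, part))
```

prints (see `examples/02_rmt_network.py` for the narrated version):

```
RMT-selected threshold s* = 0.53
network: 120 nodes, 1160 edges, 4 modules, Q = 0.603
```

The scan rejected every cutoff below 0.53 because the dense matrix's
eigenvalue spacings still showed GOE-like level repulsion (noise); at 0.53
the spectrum fragments into near-independent blocks and the spacings become
Poisson. The four modules are the three planted 20-OTU blocks plus the
co-clustered background; Q ≈ 0.6 indicates strong modular structure.

Module–trait association on a community with one trait-coupled module
(`examples/03_module_trait_association.py`):

```
module-trait correlations (trait coupled to module 2):
  module 1 (n= 15): r = -0.30, p = 0.1017
  module 2 (n= 15): r = +0.70, p = 0.0000 <-- trait-linked
  module 3 (n= 15): r = -0.11, p = 0.5703
```

The planted module carries by far the largest correlation; with coupling
β = 1.5 the attainable r is about β/√(β²+1) ≈ 0.83.

Every capability has a narrated script under `examples/`, and the full
pipeline (filter → correlate → scan → network → roles → trait association →
reports) runs from one YAML config:

```bash
micronet run --config config.yaml --seed 1 --out results_dir
```

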