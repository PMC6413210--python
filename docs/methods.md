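# Methods

This note records the models, numerical choices, and open design decisions
behind micronet, in enough detail to reproduce or criticize them.

## Similarity matrix

Abundance profiles are compared by Pearson correlation across samples. The
default input is log₁₀(relative abundance + 10⁻⁶): correlation of raw
proportions is dominated by the few most abundant taxa, while the log
transform puts rare and abundant taxa on comparable footing. The pseudocount
(default 10⁻⁶, configurable) floors zeros one decade below the smallest
observable proportion at typical depths. A raw-abundance mode is available.
Thresholding acts on |r|; the sign is carried separately and annotates edges
as cooperative (+) or competitive (−) but plays no role in threshold
selection or module detection.

Zero-variance profiles are rejected rather than silently dropped: a constant
row means the caller skipped prevalence filtering, and an r of 0/0 would be
silently wrong.

## RMT threshold selection

The selection criterion is spectral. For each cutoff *s* in a grid (default
0.30–0.99, step 0.01, bracketing thresholds reported for real cecal
communities), entries with |r| < s are zeroed, isolated rows dropped, the
diagonal restored to 1, and the matrix eigendecomposed.

**Unfolding.** NNSD statements hold for unfolded spectra (unit local mean
spacing). After collapsing degenerate eigenvalues (tolerance 10⁻⁸), the
empirical cumulative spectral function — the staircase (λᵢ, i) — is fitted
with a monotone PCHIP cubic through a decimated knot set; eigenvalues mapped
through the fit have spacings with mean 1 (exact at the endpoints, within 2%
locally). The knot count is the smoothing parameter. Too many knots chase
the staircase and whiten every spectrum; too few blur the very fluctuations
the test needs. The default of 11 knots was calibrated on simulated
benchmarks where the truth is known: correlation matrices of iid normal data
(50 variables × 200 samples, GOE statistics expected) and planted
block-modular matrices (Poisson expected). At 11 knots the chi-square test
rejects Poisson on ~95% of the GOE matrices and accepts it on all planted
block matrices tried; both error rates degrade away from this range.

**NNSD test.** Spacings are normalized to unit mean (the reference laws
describe unit-mean spacings; this makes the comparison shape-only), then
histogrammed with bin width 0.1 on [0, 3] with the tail pooled into the last
bin. Adjacent bins are further pooled until every expected count reaches 5
(Cochran's rule) — necessary for chi-square validity at the ~50-eigenvalue
scale of desk-size networks — and the statistic is referred to chi-square
with (pooled bins − 1) degrees of freedom. Reference laws: Poisson
P(d) = e^(−d); GOE via the Wigner surmise P(d) = (πd/2)e^(−πd²/4). The
unit-mean normalization makes the test mildly conservative (attained size
≈ 3.5% at nominal 5% over 1000 simulated calibration trials), which is the
safe direction for a stopping criterion.

**Selection rule.** s\* is the smallest scanned cutoff whose Poisson p-value
is ≥ α (default 0.05) while the surviving network keeps at least
`min_nodes` nodes (default 30). The full scan table (nodes, edges,
eigenvalue count, both chi-square statistics, Poisson p) is always returned,
and attached to the error if no cutoff qualifies.

A caveat the synthetic benchmarks make visible: with few eigenvalues the
test has limited power, so on small matrices whose background correlations
are already weak the scan can stop at the grid floor. The planted-recovery
check therefore asserts that s\* separates the background and block
correlation levels, not that it lands at a particular value.

## Modules

Fast-greedy agglomerative modularity maximization: start from singletons,
repeatedly apply the merge with the largest ΔQ, stop when no merge improves
Q. Q = Σₘ(e₍ₘₘ₎ − a₍ₘ₎²) over the **unweighted** graph by default (edge
presence only; weighted Q behind a flag) — edge sign never affects Q, since
observed modules in co-occurrence networks contain both signs. Determinism:
merge ties broken by the smallest (module, module) index pair; final labels
are 1-based, ordered by descending module size then smallest member id, so
repeated runs label identically. The implementation agrees exactly (to
1e-12 in Q) with an independent fast-greedy implementation on random
graphs, and reaches within 10% of the exhaustive-search optimum on planted
two-block graphs.

Greedy agglomeration is known to fall short of the global optimum on dense
unstructured (Erdős–Rényi) graphs; validation therefore distinguishes
"matches the canonical algorithm" (asserted on arbitrary graphs) from
"near-optimal" (asserted on modular graphs, the structure this pipeline
targets).

## Node roles

Zᵢ is the z-score of a node's within-module link count against its module
peers, using the population standard deviation (the convention of the
Guimerà–Amaral formulation); modules with zero spread give Zᵢ = 0.
Pᵢ = 1 − Σₜ(k₍ᵢₜ₎/kᵢ)². Role quadrants at Zᵢ = 2.5 and Pᵢ = 0.62:
peripheral (low/low), module hub (high Zᵢ), connector (high Pᵢ), network hub
(both). Values exactly at a cutoff go to the hub/connector side, making the
four regions exhaustive and disjoint (the source convention states strict
inequalities only for peripherals).

## Module eigengenes and trait association

A module eigengene is the first right singular vector of the z-scored
member × sample matrix, scaled to unit variance — one representative value
per sample. Orientation: flipped if its mean correlation with member
profiles is negative; exact ties break toward the sign of the
lexicographically first member. Variance explained is the leading
eigenvalue's share. Module–trait association is Pearson r of eigengene vs
trait with the two-tailed t-transform p (t = r√((n−2)/(1−r²)), n−2 df); a
permutation p is available behind a flag for small n.

Per-OTU trait significance is the squared Pearson correlation of the OTU's
profile with the trait. The Mantel link between topology and trait uses
D₁ = pairwise |difference| of OTU significances and D₂ = pairwise
|difference| of node degree — the named quantities turned into distances in
the most literal way, since no construction is standard. The Mantel
statistic is the Pearson correlation of lower triangles; rows and columns
of D₂ are permuted jointly; the one-tailed p is (1 + #{r_perm ≥ r_obs}) /
(n_perm + 1), so p can never be zero. Type-I error is calibrated to
[0.03, 0.07] at α = 0.05 in the acceptance suite.

## Two-group statistics

Wilcoxon rank-sum with midranks. Exact two-sided p by full enumeration of
all C(n, nₓ) group assignments when n ≤ 12 and the pooled sample is
tie-free; otherwise the normal approximation with tie correction and a 0.5
continuity correction. Multiple testing: Benjamini–Hochberg step-up
(statsmodels), the standard choice when the correction method is otherwise
unspecified. Effect size is the fold change of group mean percent
composition (treatment/control; flagged undefined when the control mean is
zero). Bootstrapped LDA effect scores are deliberately not reproduced;
significance filtering is by q-value.

## Tumor growth

Volume from calliper pairs by the ellipsoid approximation
V = 0.523·L·W² (cm³); if width exceeds length the axes are swapped with a
warning rather than rejected, since the convention (length = major axis) is
easy to violate at the bench. Growth is modelled as single-phase exponential
V(t) = V₀e^(kt), fitted by nonlinear least squares initialized from the
log-linear regression (a power-law alternative is configurable). Two arms
are compared by the extra-sum-of-squares F test: F = [(RSS_shared −
RSS_sep)/2] / [RSS_sep/(n−4)], p from F(2, n−4).

## Synthetic data generator

The generator emulates a two-arm xenograft microbiome study at desk scale:
defaults of 9 samples per group and 767 OTUs (eight planted modules of
30…7 members plus 640 background OTUs), sequencing depth 50 000, with one
trait-coupled module.

Model, per OTU i and sample j: log-abundance x᎐ij = μᵢ + λ·f₍m(i),j₎ + εᵢⱼ
with baselines μᵢ ~ N(0,1) drawn once per OTU (realistic abundance spread),
module factors f ~ N(0,1) per (module, sample), noise ε ~ N(0, σ²); counts
are one multinomial draw per sample of softmax(x) at the stated depth
(compositional, fixed-depth, like amplicon data — not independent Poisson);
dropout zeroes cells post-sampling with fixed probability, reproducing
prevalence-filter behaviour. The trait is β·f₍m\*,j₎ + N(0,1), so its
correlation with the linked factor tends to β/√(β²+1); β defaults to 1.5
(attainable r ≈ 0.83, comfortably in the regime where a single-module
association like r ≈ 0.8 at n = 9 is reachable). λ (default 1.5) and σ
(default 0.5) put within-module |r| near 0.9 and background pair
correlations near sampling noise.

The two-group variant shares μᵢ and module memberships across arms (the
same underlying community), drawing independent factors and noise per arm;
a designated module can receive a log-abundance offset in the treatment arm
only. That module's baseline is lowered (default −2.5 in log units) so the
responding taxa are **rare at baseline** — a rare-taxon bloom. This is both
the observed regime (a taxon rising from ~0.02% to ~1% of the community)
and a statistical necessity: boosting an abundant module drags every other
relative abundance down through compositional closure, so "only the shifted
taxa change" is only true when the shifted mass stays small.

What the generator does **not** emulate: phylogenetic correlation between
taxa, overdispersion beyond multinomial, sample-to-sample depth variation,
batch effects, and zero-inflation tied to abundance (dropout here is
uniform). Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes, not that real cecal data satisfies those
assumptions.

## Problem sizes in the validation suites

Calibration and recovery checks run at sizes chosen to make the statistics
meaningful while staying desk-scale: NNSD calibration on 5000-spacing draws
× 100 trials; planted-threshold recovery on 60-OTU, three-block matrices
over 5 seeds; exhaustive modularity comparison on 8-node graphs (Bell(8) =
4140 partitions per graph, 20 graphs); Zi/Pi brute-force agreement on 50
random partitioned graphs; Mantel type-I over 2000 null trials at 199
permutations; trait-module recovery at n = 30 samples over 10 seeds; exact
Wilcoxon enumeration for all splits of n ≤ 10.

## Known limitations

- NNSD-based selection is underpowered below ~40 eigenvalues; the scan can
  stop at the grid floor for small, weakly correlated matrices. Inspect the
  scan table, not just s\*.
- The similarity measure is Pearson on log abundances; compositional
  effects can induce spurious negative correlation among dominant taxa
  (no CLR or proportionality alternative is provided).
- Greedy modularity is a local optimizer; near-degenerate modular
  structures may merge.
- The Mantel distance construction for topology vs trait is one defensible
  choice among several; its p-value should be read as a screening statistic.
- PD_whole_tree diversity is out of scope (no phylogeny is handled).
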