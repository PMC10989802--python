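# Methods

This note documents the statistical procedures implemented in `netkomp`,
the choices made where several defensible variants exist, and what the
synthetic generator does and does not emulate.

## Data model

A `FeatureTable` couples a feature × sample abundance matrix (non-negative
reals) with per-feature taxonomy (ranks Kingdom…Species, missing ranks
stored as empty strings and reported as "unclassified"), per-sample
metadata (numeric abiotic variables and categorical group columns) and an
optional symmetric feature distance matrix. Assembly intersects the name
sets of all parts and logs what was dropped; it is idempotent. A
`CooccurrenceNetwork` is an undirected simple graph with canonical edge
keys (endpoint IDs in lexicographic order, no self-loops) whose `sign`
attribute is derived from the weight, and a `NetworkCollection` is an
insertion-ordered label → network map — the unit of every comparison.
Distance matrices may hold any symmetric quantity (patristic distances,
niche overlap, …); they are used as given and never rescaled.

## Network construction

* **Filtering.** Features must be non-zero in at least `min_prevalence` of
  the samples and reach `min_mean_relabund` mean relative abundance
  (per-sample proportions averaged over samples). Defaults: prevalence
  0.1, relative abundance 0. These are conventions, not reproductions of
  any published threshold, and are fully overridable.
* **Correlation networks.** Pearson directly; Spearman as Pearson on
  within-feature average ranks. Two-sided p-values use the t
  approximation t = r√((n−2)/(1−r²)) with n−2 degrees of freedom —
  standard at n ≥ 10; at least 4 samples are required. Zero-variance
  features get r = 0, p = 1 against everything and therefore never form
  edges. Benjamini–Hochberg adjustment pools the entire upper triangle of
  the filtered feature set as one family; the edge rule
  |r| ≥ r<sub>thr</sub> AND p<sub>adj</sub> < p<sub>thr</sub> is applied to
  both quantities simultaneously. The magnitude |r| is thresholded (not
  signed r) so both positive and negative associations survive. Isolated
  features remain as nodes. Correlations within 10⁻¹² of ±1 are snapped to
  exactly ±1 so that the boundary threshold r<sub>thr</sub> = 1 behaves as
  "perfect correlations only".
* **Bray-Curtis networks.** Similarity s = 1 − Σ|x<sub>i</sub> −
  x<sub>j</sub>| / Σ(x<sub>i</sub> + x<sub>j</sub>) over samples on raw
  abundances; edges kept at s ≥ r<sub>thr</sub>, all positive. A pair of
  all-zero profiles has undefined dissimilarity; its similarity is defined
  as 0 and logged.
* **Per-group construction** subsets samples first and filters per group,
  so each group's network reflects its own prevalence structure;
  collection order follows first appearance of the group labels.

## Topology

Module detection is greedy modularity maximization
(Clauset–Newman–Moore via networkx) on the unweighted, unsigned simple
graph; negative edges count as present (a positive-only variant is
exposed as a flag). Isolated nodes become singleton modules. Module IDs
are deterministic: communities sorted by decreasing size, ties broken by
their lexicographically smallest member. Modularity Q is the unweighted
Newman definition; an edgeless graph has Q = 0 by convention.

Z<sub>i</sub> uses the population (n-denominator) standard deviation of
within-module degrees; modules of size 1 or zero spread give
Z<sub>i</sub> = 0, isolated nodes get P<sub>i</sub> = 0, so every node is
classifiable without division by zero. Role thresholds are Z = 2.5 and
P = 0.62. The corner Z ≤ 2.5 with P exactly 0.62 is not covered by the
published rule wording ("P < 0.62" for peripherals vs "P > 0.62" for
connectors); it is assigned peripheral and flagged in the log rather than
silently guessed. Betweenness is unweighted and unnormalized by default
(a normalization flag exists); path length and diameter are computed on
the largest connected component and reported as NaN when undefined.

## Cross-network comparison

Edges match across networks on their canonical endpoint pair; sign is
ignored by default and enforced with `match_sign`. Venn regions are exact
membership signatures (frozensets of labels); with more than five
networks the counts remain exact, only a drawable diagram stops making
sense. `subset_network` extracts the full intersection or one exact
region; attributes of an extracted edge come from the first collection
member containing it — weights differ between methods, so one rule has to
be fixed, and this one is recorded in the provenance.

Edge distances are looked up symmetrically in the supplied matrix; edges
with endpoints missing from the matrix are dropped and logged. Group
differences (network, or network × sign) are tested with one-way ANOVA
followed by **Duncan's new multiple range test**: ordered means, critical
range R<sub>p</sub> = q\*(p, df<sub>error</sub>)·√(MSE/n<sub>h</sub>)
with n<sub>h</sub> the harmonic mean group size and q\* the
studentized-range quantile at Duncan's protection level
1 − (1 − α)<sup>p−1</sup> for a span of p means. A pair is declared
non-significant if any enclosing span is non-significant (the standard
protection rule); letters then correspond to the maximal non-significant
intervals in mean order, ties in means broken lexicographically, which is
what the insert-and-absorb compact-letter-display algorithm produces for
a range test. Tukey's HSD is available as an alternative. When MSE = 0
the F statistic is undefined and all groups share one letter. With two
groups Duncan's range reduces to the pooled two-sample t-test, which the
test-suite verifies.

Taxon sources of edges are tallied as unordered rank-label pairs of the
endpoints, per sign, divided by the total number of edges of that sign in
that network; a network without such edges yields NaN ratios with a
warning.

## Module eigengenes and environment correlation

The eigengene of a module is the first principal component of its
members' abundance profiles, computed after z-scoring each feature across
samples, with sample scores rescaled to unit variance; its sign is fixed
so it correlates non-negatively with the module's mean standardized
profile, and the variance-explained share is reported. Preprocessing is
configurable: `raw_z` (default) z-scores raw abundances; `relabund_z`
converts to per-sample relative abundances first. The default is raw
z-scoring because closure of relative abundances couples modules whose
totals co-vary: on generated data with three latent-driven modules the
relative-abundance variant depresses eigengene–latent correlation from
≈0.98 to ≈0.8. For depth-varying count data, normalize depth upstream or
use `relabund_z` deliberately.

Environment correlation computes Pearson r and two-sided p per (entity,
variable) on the shared samples, BH-adjusts per variable (one family per
metadata column), and draws stars from the raw p-values at 0.05 / 0.01 /
0.001 by default — the adjusted grid is always produced alongside and can
drive the stars instead. Zero-variance entities or variables give NaN
with a warning.

`modules_to_communities` splits the feature table by module (all samples
kept) for composition summaries at any rank. Functional annotation
consumes a user-supplied (rank, label, function) mapping file with exact
label matching; no functional database is bundled.

## Per-sample subnetworks

A sample induces the subgraph on the features with abundance strictly
greater than `min_abund` (default 0, i.e. simple presence). Each sample
is matched to the network labelled with its group; unmatched samples are
skipped with a warning. Properties of empty or singleton subnetworks
report counts of 0/1 and NaN for densities and path metrics rather than
fabricated values. The property table feeds the same correlation grid as
eigengenes.

## Synthetic generator

The generator emulates a grouped survey: features are partitioned into
modules; module m has a latent factor over samples that is correlated
(default 0.8) with a stored environmental variable; feature abundances
are softplus(1.5·g + 2) with g = ±√w·latent + √(1−w)·σ·ε, so the target
within-module Gaussian-scale correlation is w (default 0.8, idiosyncratic
noise σ default 1). The softplus link keeps abundances non-negative while
only mildly attenuating correlations. At σ = 0 all same-loading members
of a module are identical, giving exactly |r| = 1; the default
negative-loading fraction is therefore 0 (sign-flipped members would make
that limit inexact through the nonlinearity) and negative associations
are planted by setting it explicitly. Taxonomy assigns each module a
predominant phylum with 10% mixing; the tree joins per-module random
bifurcating subtrees (exponential branch lengths, scale 0.1) by long
stems (length 1), so within-module patristic distances are stochastically
smaller than between. Default sizes are 60 features, 40 samples, 3
modules, 3 sample groups — small enough that every stage runs in seconds
while leaving non-trivial per-group sample sizes (13–14).

What the generator does **not** emulate: compositional closure with
varying sequencing depth, zero inflation and overdispersed counts,
phylogenetically conserved abundances beyond the block structure, or
group-specific association structure (all groups share the planted
modules). Passing recovery tests therefore demonstrates correctness of
the algorithms under clean block-correlated conditions, not robustness of
correlation networks to the known pathologies of sequencing data — the
toolkit deliberately leaves composition-aware construction methods to
dedicated external tools.

## Numerical conventions

Edge keys are lexicographic endpoint pairs. TSV is tab-separated UTF-8
with "." decimals and unquoted IDs. Patristic distances require explicit
branch lengths on every non-root edge — no silent default of 1. All
round-trips (tables and network formats) are lossless for names, signs
and weights to 10⁻⁹. Random procedures (generator, module detection
entry point) take explicit seeds; greedy modularity itself is
deterministic given the canonical node ordering used to build the
unsigned graph.
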