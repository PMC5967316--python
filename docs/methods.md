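# Methods

This note records what the package computes, the conventions chosen where a
published description is silent, what the synthetic generator does and does
not emulate, and the numerical details a maintainer would need.

## Gene sets

**DNM genes.** Two conditions, both required: per-gene TADA-style p strictly
below `p_dnm` (default 0.05), and an expression call in ≥ 1 site. The
boundary is strict: p = 0.05 is excluded.

**CV genes.** A gene qualifies when at least one variant with p strictly
below `p_gwas` (default 5 × 10⁻⁸) falls inside its window, and the gene is
expressed in ≥ 1 site. Coordinates are 0-based half-open `[start, end)` (BED
convention) and the window test is `pos ∈ [start − w, end + w)` with
w = 35,000 bp: inclusive at the upstream edge, exclusive at `end + w`. The
source analyses do not state a boundary convention; this one is flagged here
because a variant at exactly `start − 35,000` is *included* while one at
`end + 35,000` is not. The window is applied symmetrically regardless of
strand (strand is never used). The per-gene p is the minimum over the gene's
significant variants — needed for subgrouping; nothing in the published
description says which variant represents the gene.

**Subgroups.** CV genes are sorted by −log₁₀(p) (ties broken by symbol) and
cut into k = 7 contiguous chunks via `numpy.array_split`, so sizes differ by
at most one. Subgroup 1 is the least significant. Quantile (equal-count)
binning was chosen over equal-width bins because the target description is
"roughly similar number of genes" per group.

**Overlap.** For pairwise edge/path analyses, genes in both sets are removed
from both (`resolve_overlap(..., "exclude_shared")`); for seeding the
subnetwork, the deduplicated union is used. The shared genes are always
reported.

## Expression

A gene is *expressed* at a site when its RPKM exceeds `rpkm` (default 1.0,
strict >) in at least `min_samples` samples (default 1). More stringent
cutoffs are a parameter change, not a separate code path.

Tissue z-scores standardize each gene's per-tissue mean expression with the
sample (n − 1) standard deviation — the ddof is a choice, documented because
the published formula writes only "sd". Genes with constant tissue means get
z = 0 everywhere (no specificity signal rather than a missing value).
Group-versus-rest tissue comparisons use one-sided Welch t-tests
("members more specific") with Benjamini–Hochberg correction over the full
set × tissue grid.

Co-expression is |PCC| over all samples of a site, including values ≤ 1:
the expression call gates which *nodes* enter the CoPPI, not which samples
enter the correlation. Whether the original analysis restricted the
correlation input is not stated; gating nodes only is the simpler reading
and keeps the correlation estimate full-rank. Zero-variance genes yield
co-expression 0 with a logged warning (a total pipeline without fabricated
correlation).

## CoPPI

Edges whose endpoints are both expressed keep their |PCC| weight; all other
edges are removed, and nodes isolated by the removal are dropped (mirroring
the parent network's removal of isolated nodes — the published construction
removes edges and is silent on the resulting isolates). Edge weights are
clipped to [0, 1] against floating-point overshoot.

## Network characterization

**Betweenness** is the raw count of shortest paths passing through a node:
for every unordered pair (s, t) and internal node v with
d(s,v) + d(v,t) = d(s,t), the contribution is σ(s,v) · σ(v,t). This follows
the verbal definition "the number of shortest paths going through a node"
and is *not* the conventional fractional betweenness (which divides by
σ(s,t)); the two differ whenever a pair has several shortest paths. The
implementation runs BFS from every node and accumulates the
σ-product per source with vectorized distance checks — O(n·m) for the BFS
plus O(n³) bitwise accumulation, practical to a few thousand nodes. The test
suite checks it against exhaustive path enumeration. `log_betweenness` is
ln(betweenness + 1); +1 keeps leaves (betweenness 0) finite, and the log
base is a display choice. Betweenness is computed on the unweighted PPI,
not on CoPPIs.

**Group tests** are two-sided Wilcoxon rank-sum (Mann–Whitney) tests of a
set against all other network genes. Sidedness is not stated in the source;
two-sided is the conservative default.

**Randomization.** The empirical p is the exact proportion of `n_draws`
(default 10,000) random same-size sets whose statistic is ≥ the observed
one — "≥", one-sided, high = extreme, and no add-one smoothing, so a result
of 0 is reported as 0 and read as "< 1/n_draws". Degree-matched mode sorts
nodes by (degree, id), splits them into four near-equal quartiles, and draws
the observed set's per-quartile counts exactly in every replicate; a
two-set variant draws both sets disjointly with their own compositions.
Under a true null the empirical p is uniform; the acceptance suite verifies
this with a KS test. Note that quartile matching controls degree only at
stratum resolution: a set sitting at the extreme top of the fourth quartile
remains extreme after matching.

**Edge co-expression tests.** Welch t-tests of CoPPI edge weights, group
edges versus all other edges, Bonferroni-corrected across the full
(site, group) grid of within-DNM, within-CV and DNM–CV-cross tests. Groups
covering every edge (empty complement) are reported as missing.

## Subnetwork growth

Candidates are non-seed nodes with ≥ 2 seed interactors; r1 and r2 are
computed once against the original seed set and kept fixed during growth
(the candidate scores refer to the genes of interest, not to the growing
subnetwork). Filter boundaries follow the printed inequalities exactly:
r1 ≥ 1.2 inclusive, r2 > 0.1 strict. If a candidate's overall mean edge
weight is 0, r1 is defined as 0 (no co-expression evidence at all).

A seed counts as **linked** when its connected component in the induced
subgraph contains ≥ 2 seeds. The published text never defines "#linked";
this choice makes r3 = 1 achievable, excludes trivially isolated seeds, and
does not credit a seed connected only to linkers. Seeds absent from the
CoPPI (unexpressed at that site) are excluded from both the numerator and
denominator of r3. `mean(e_subnetwork)` averages over *all* CoPPI edges
induced on seed ∪ linker nodes — the simplest reading of "average weight of
edges in the subnetwork" — not only candidate-incident edges.

The greedy loop evaluates s for every remaining candidate (incrementally,
via a union-find over the current node set with per-component seed counts,
so one evaluation costs O(degree)), accepts the argmax, and stops when the
best relative gain `(s_new − s_old)/max(s_old, 1e−12)` falls below
`stop_ratio` (default 0.005; 0.002 is the tested sensitivity value) or no
candidate improves s. Ties break by larger r2, then lexicographically
smallest node id — growth is fully deterministic. The final subnetwork is
re-scored from scratch in a fixed edge order so results are identical across
processes. Random-seed baselines draw seeds uniformly from the CoPPI nodes
(expressed genes; whether the original drew from all nodes is unstated) and
run the identical find → filter → grow pipeline.

"Dominates" in baseline comparisons means Pareto dominance on the pair
(linked-seed count, s): ≥ in both coordinates, > in at least one. Ties in
the integer linked count are common when both runs saturate the reachable
seeds, so requiring strict inequality in both coordinates would make the
comparison depend on those ties rather than on the co-expression signal.

## Synthetic data

The generator produces what the analysis consumes, with planted truth:

- **Topology:** preferential attachment (heavy-tailed, like PPI networks —
  the analyses are degree-sensitive) topped up with uniform random edges to
  hit the exact requested edge count. Defaults are reference scale: 10,314
  nodes, 51,637 edges, mean degree ≈ 10.
- **Expression:** RPKM = exp(μ + σ·x) with x standard normal. Planted module
  genes replace x by `sqrt(1 − s²)·ε + s·f` with a per-site shared factor f,
  so their pairwise log-scale correlation is exactly s² (s =
  `coexpr_strength`); the variance-preserving form keeps the marginal
  distribution independent of s, and |PCC| on the RPKM scale rises
  monotonically with s. Per site, a fraction `unexpressed_fraction` of
  non-planted genes is overwritten with Uniform(0, 1) values so they fail
  the RPKM > 1 call. Planted DNM/CV/module genes are exempt from this mask,
  guaranteeing that planted truth is exactly recoverable by the downstream
  filters.
- **Variants:** one synthetic chromosome, 200 kb gene spacing, 10 kb bodies,
  so ± 35 kb windows never overlap and window tests are unambiguous. Planted
  DNM genes draw p uniform on [10⁻⁶, 0.05), others on [0.05, 1). Each
  planted CV gene gets one variant placed uniformly in its window with
  −log₁₀(p) uniform on [7.302, 29.75] — the lower bound sits just above
  −log₁₀(5 × 10⁻⁸) = 7.3010 so every planted variant is genuinely
  significant under the strict filter; decoy variants have p ≥ 5.1 × 10⁻⁸.
  Planted DNM and CV sets are drawn uniformly from the gene universe with an
  exact requested overlap.
- **Seed placement for module-recovery studies:**
  `sample_connected_seed_genes` snowball-samples a connected interactome
  neighborhood. This emulates a disease module — risk genes interacting with
  each other more than randomly expected. It matters for the baseline
  comparison: with seeds scattered uniformly, random-seed baselines link
  essentially all their seeds (noise-level edge weights carry no mean-weight
  penalty during growth) while a high-co-expression seed set is penalized
  for adding noise linkers, so no co-expression strength can make a
  scattered planted set dominate the baselines on linked count. A connected
  planted module is both the realistic emulation and the configuration in
  which the dominance comparison is informative.

What the generator does **not** emulate: multi-factor or hierarchical
co-expression structure, linkage disequilibrium between variants, trio-level
mutation processes, strand, multi-transcript gene models, or realistic
per-tissue expression profiles. Passing tests therefore demonstrate that the
algorithms recover the structure they are defined to recover — not that real
schizophrenia data would yield any particular biological result.

## Determinism and problem sizes

Every random draw flows from explicit integer seeds through
`numpy.random.default_rng`; per-stage streams are derived with
`SeedSequence` so stages are independently reproducible. Identical configs
give byte-identical output bundles across processes (summation orders are
fixed; no wall-clock or hash-order dependence).

Tests and the acceptance script run the statistics at reduced problem sizes
chosen as the package's own benchmark configurations: gene-set recovery at
full reference scale (10,314 genes; the filters are cheap), network
characterization on 300–800-node graphs (the O(n³) betweenness accumulation
is the binding cost), module recovery on a 300-gene / 1,500-edge network
(reference mean degree) with 40 planted seeds, 100 samples per site and 100
baselines per replicate. The pipeline defaults (10,000 permutations, 100
baselines, 12 sites) are the reference analysis values.

## Known limitations

- Path-count betweenness grows combinatorially with redundant shortest
  paths; σ is accumulated in float64, exact up to 2⁵³ paths.
- The greedy growth is a heuristic: step-wise optimal (verified against
  brute force) but with no global optimality guarantee, matching the
  original design; exact search and Steiner-tree formulations are out of
  scope.
- Degree-quartile matching controls degree at stratum resolution only.
- The unexpressed mask exempts planted genes, so measured unexpressed
  fractions undershoot the nominal fraction by the planted share of the
  gene universe.
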