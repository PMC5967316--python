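# coppilink

Tools for asking whether two very different classes of risk variants for a
complex disease — **de novo mutations** (DNMs, found by sequencing family
trios) and **common variants** (CVs, found by genome-wide association
studies) — converge on the same molecular networks. The package characterizes
the genes carrying each variant class inside a human protein–protein
interaction (PPI) network, weights that network by brain co-expression, and
grows a subnetwork that links as many of both gene groups as possible with
high co-expression. It was built with schizophrenia genetics in mind but
operates on generic inputs: any undirected PPI edge list, any set of
genes × samples RPKM matrices, a per-gene de novo association table and a
GWAS summary table.

Because the real inputs are large controlled-access downloads, the package
ships a first-class synthetic generator that emulates all four inputs with
planted, recoverable structure — a scale-free PPI, log-normal RPKM with a
planted co-expressed module, TADA-like p-values and variant positions planted
inside gene windows — so the entire analysis is testable end to end.

## The model

**Gene sets.** A gene is *expressed* at a site when RPKM > 1 in ≥ 1 sample.
DNM genes are genes with a per-gene TADA p < 0.05 that are expressed in at
least one spatiotemporal site. CV genes have ≥ 1 variant with p < 5 × 10⁻⁸
inside the gene body ± 35 kb and are likewise expressed somewhere. CV genes
are split into 7 near-equal subgroups by −log₁₀(p). Tissue specificity of a
gene is `z_i = (expr_i − mean(Expr)) / sd(Expr)` over its per-tissue mean
expression.

**CoPPI.** A co-expression-weighted PPI for one site: every edge is weighted
by |PCC| (absolute Pearson correlation) of its endpoints' expression at that
site; edges touching unexpressed genes are removed.

**Network characterization.** Node degree and betweenness (the *count* of
shortest paths through a node) of the gene sets, compared with other genes by
Wilcoxon rank-sum tests and by empirical p-values from 10,000 random
same-size gene sets — optionally drawn to match the observed set's
composition across four node-degree quartiles, which absorbs degree-driven
signal.

**Subnetwork growth.** With seeds = DNM ∪ CV genes in the network, candidate
linker genes are non-seeds with ≥ 2 seed interactors, scored

    r1 = mean(e_cand,seed) / mean(e_cand)            (co-expression specificity)
    r2 = r1 · |interactors ∩ seeds| / |interactors|  (degree control)

and kept when r1 ≥ 1.2 and r2 > 0.1. A node set is scored
`s = r3 · mean(e_subnetwork)` where `r3` is the fraction of seeds lying in a
connected component (of the induced subgraph) containing ≥ 2 seeds. Growth
greedily adds the candidate maximizing `s` until the relative gain drops
below 0.5%. The result is benchmarked against 100 subnetworks grown by the
identical procedure from random seed sets of the same size.

## Worked example

Run the whole pipeline on synthetic data (500 genes, 2,500 interactions,
12 spatiotemporal sites, 25 planted DNM genes, 40 planted CV genes sharing 5,
co-expression strength 0.8):

```bash
coppi-linker all --config examples/config.yaml --outdir demo/run --seed 42
# pipeline complete: 12 per-site subnetworks, summary at demo/run/summary.json
```

`demo/run/summary.json` then contains (abridged):

```
gene_sets:  {'n_dnm': 25, 'n_cv': 40, 'n_shared': 5, 'n_seeds': 60,
             'cv_subgroup_sizes': [6, 6, 6, 6, 6, 5, 5], ...}
subnetworks['ST1_FC']:
            {'n_linked': 49, 'n_seeds_in_coppi': 60, 'n_linkers': 2,
             'r3': 0.817, 'mean_edge_weight': 0.527, 's': 0.431,
             'n_baselines_dominated': 4}
```

Reading: the filters recovered exactly the planted 25 DNM and 40 CV genes
(5 shared), and in the stage-1 frontal-cortex CoPPI the greedy growth linked
49 of the 60 seed genes through 2 linkers at mean co-expression 0.53, giving
subnetwork score s = 0.82 × 0.53 ≈ 0.43. Per-site outputs (weighted edge
lists, node roles, growth traces, randomization results) are written under
the run directory.

The same stages are available individually as `coppi-linker
synth | sets | coppi | stats | link`, e.g.

```bash
coppi-linker synth --outdir data --seed 3
coppi-linker link --coppi coppi.tsv --dnm sets.tsv --cv sets.tsv \
    --r1 1.2 --r2 0.1 --stop 0.005 --baseline 100 --seed 1 --outdir out
```

## Layout

- `src/coppilink/synthetic.py` — synthetic input generator (planted truth)
- `src/coppilink/genesets.py` — DNM/CV selection, window mapping, subgroups
- `src/coppilink/expression.py` — expression calls, tissue z-scores, |PCC|
- `src/coppilink/coppi.py` — co-expression-weighted PPI construction
- `src/coppilink/netstats.py` — degree/betweenness, randomization nulls
- `src/coppilink/subnetwork.py` — candidate scoring and greedy growth
- `src/coppilink/pipeline.py`, `cli.py` — orchestration and console script
- `docs/methods.md` — modelling choices, parameters and limitations
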