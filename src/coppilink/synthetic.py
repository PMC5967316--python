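"""Synthetic input generator.

Emulates the four inputs of the analysis with controllable statistical
structure:

* a scale-free PPI network (preferential attachment topped up with random
  edges to hit an exact edge count);
* per-site RPKM expression matrices with a planted co-expressed module —
  planted genes share a per-site latent factor so that their pairwise log-
  scale correlation equals ``coexpr_strength ** 2`` — and a per-site fraction
  of unexpressed genes (all RPKM <= 1);
* a DNM table with TADA-like per-gene p-values where exactly
  ``n_dnm_genes`` planted genes fall below 0.05;
* a GWAS variant table plus BED-like gene annotation where exactly
  ``n_cv_genes`` planted genes carry a genome-wide significant variant inside
  their +/-35 kb window, overlapping the DNM set in exactly ``n_overlap``
  genes.

All randomness is drawn from streams derived from ``config.rng_seed``;
identical configs produce byte-identical artifacts. Planted DNM/CV/module
genes are exempt from the unexpressed mask so that planted truth is
recoverable exactly by the downstream filters.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import math

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .config import SyntheticConfig
from .expression import ExpressionPanel

# fixed synthetic chromosome layout: 200 kb gene spacing, 10 kb bodies, so
# +/-35 kb windows of adjacent genes never overlap
_GENE_SPACING = 200_000
_GENE_BODY = 10_000
_GENE_OFFSET = 50_000

_STAGES = ("ST1", "ST2", "ST3")
_REGIONS = ("FC", "SC", "SM", "TP")

# -log10 p range for planted significant variants; the lower bound sits just
# above -log10(5e-8) = 7.3010 so every planted variant is genuinely
# genome-wide significant under the strict < 5e-8 filter
_PLANTED_NEGLOG10_RANGE = (7.302, 29.75)


def _rng(config: SyntheticConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.rng_seed) & 0x7FFFFFFF, *stream])


def gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_ppi_network(config: SyntheticConfig) -> nx.Graph:
    """Scale-free undirected PPI with exactly the configured node/edge counts."""
    n, m_target = config.n_genes, config.n_edges
    if n < 10:
        raise ValueError("n_genes must be >= 10")
    if m_target < n - 1:
        raise ValueError("n_edges must be >= n_genes - 1 (connected lower bound)")
    max_edges = n * (n - 1) // 2
    if m_target > max_edges:
        raise ValueError(
            f"infeasible edge count: {m_target} > n*(n-1)/2 = {max_edges}"
        )
    m = max(1, m_target // n)
    while m > 1 and m * (n - m) > m_target:
        m -= 1
    rng = _rng(config, 0)
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    # top up with random non-edges to reach the exact count
    while g.number_of_edges() < m_target:
        u, v = rng.integers(0, n, size=2)
        if u != v and not g.has_edge(u, v):
            g.add_edge(int(u), int(v))
    names = gene_names(n)
    return nx.relabel_nodes(g, {i: names[i] for i in range(n)})


def sample_connected_seed_genes(
    network: nx.Graph, n: int, rng: np.random.Generator
) -> list[str]:
    """Snowball-sample ``n`` genes forming a connected induced subgraph.

    Emulates a disease module: the planted seed genes occupy one interactome
    neighborhood rather than scattering uniformly, mirroring the observation
    that risk genes interact with each other more than randomly expected.
    Starts from a random node and repeatedly absorbs a random frontier
    neighbor, so the induced subgraph of the result is always connected.
    """
    nodes = sorted(network.nodes)
    if n > len(nodes):
        raise ValueError("n exceeds network size")
    start = nodes[int(rng.integers(len(nodes)))]
    seen = {start}
    frontier = sorted(network.neighbors(start))
    while len(seen) < n and frontier:
        pick = frontier[int(rng.integers(len(frontier)))]
        seen.add(pick)
        frontier = sorted(
            {v for u in seen for v in network.neighbors(u)} - seen
        )
    return sorted(seen)


def _planted_variant_sets(
    config: SyntheticConfig, genes: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Deterministic planted DNM and CV gene lists (exact overlap)."""
    n_needed = config.n_dnm_genes + config.n_cv_genes - config.n_overlap
    if n_needed > len(genes):
        raise ValueError(
            "n_dnm_genes + n_cv_genes - n_overlap exceeds the gene universe"
        )
    rng = _rng(config, 1)
    perm = rng.permutation(np.asarray(genes, dtype=object))
    dnm = list(perm[: config.n_dnm_genes])
    start = config.n_dnm_genes - config.n_overlap
    cv = list(perm[start : start + config.n_cv_genes])
    return dnm, cv


def _planted_module(config: SyntheticConfig, genes: Sequence[str]) -> list[str]:
    if config.planted_seed_genes is not None:
        module = list(config.planted_seed_genes)
        missing = set(module) - set(genes)
        if missing:
            raise ValueError(
                f"planted_seed_genes outside gene universe: {sorted(missing)[:5]}"
            )
        return module
    dnm, cv = _planted_variant_sets(config, genes)
    return sorted(set(dnm) | set(cv))


def _site_metadata(n_sites: int) -> pd.DataFrame:
    rows = []
    if n_sites == len(_STAGES) * len(_REGIONS):
        for stage in _STAGES:
            for region in _REGIONS:
                rows.append(
                    {"site_id": f"{stage}_{region}", "stage": stage,
                     "region": region}
                )
    else:
        for i in range(n_sites):
            rows.append(
                {"site_id": f"S{i + 1:02d}", "stage": f"ST{i + 1}",
                 "region": "ALL"}
            )
    return pd.DataFrame(rows)


def generate_expression_panel(
    network: nx.Graph, config: SyntheticConfig
) -> ExpressionPanel:
    """Log-normal RPKM per site with the planted co-expression module.

    Planted module genes share a per-site standard-normal latent factor with
    loading ``coexpr_strength`` (variance-preserving on the log scale), so
    their pairwise |PCC| rises monotonically with the strength. A random
    ``unexpressed_fraction`` of non-planted genes is forced to RPKM <= 1 in
    every sample of a site.
    """
    if config.samples_per_site < 3:
        raise ValueError("samples_per_site must be >= 3 (PCC is degenerate)")
    genes = sorted(network.nodes)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    module = _planted_module(config, genes)
    dnm, cv = _planted_variant_sets(config, genes)
    exempt = set(module) | set(dnm) | set(cv)
    maskable = np.asarray([i for g, i in idx.items() if g not in exempt])
    module_idx = np.asarray([idx[g] for g in module], dtype=int)
    s = config.coexpr_strength
    meta = _site_metadata(config.n_sites)
    sites: dict[str, pd.DataFrame] = {}
    for site_i, site in enumerate(meta["site_id"]):
        rng = _rng(config, 2, site_i)
        m = config.samples_per_site
        eps = rng.standard_normal((n, m))
        factor = rng.standard_normal(m)
        log_x = eps.copy()
        if len(module_idx):
            log_x[module_idx] = (
                math.sqrt(1.0 - s * s) * eps[module_idx] + s * factor[None, :]
            )
        log_x = (
            config.background_rpkm_logmean
            + config.background_rpkm_logsd * log_x
        )
        x = np.exp(log_x)
        n_mask = int(round(config.unexpressed_fraction * n))
        n_mask = min(n_mask, len(maskable))
        if n_mask:
            chosen = rng.choice(maskable, size=n_mask, replace=False)
            x[chosen] = rng.uniform(0.0, 1.0, size=(n_mask, m))
        cols = [f"{site}_s{j + 1}" for j in range(m)]
        sites[site] = pd.DataFrame(x, index=pd.Index(genes, name="gene"),
                                   columns=cols)
    return ExpressionPanel(sites=sites, metadata=meta)


def generate_variant_tables(
    network: nx.Graph, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """DNM table, GWAS variant table and gene annotation with planted truth."""
    genes = sorted(network.nodes)
    dnm_genes, cv_genes = _planted_variant_sets(config, genes)
    dnm_set, cv_set = set(dnm_genes), set(cv_genes)

    # annotation: one synthetic chromosome, fixed spacing
    starts = _GENE_OFFSET + _GENE_SPACING * np.arange(len(genes), dtype=np.int64)
    ann = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + _GENE_BODY,
            "gene": genes,
        }
    )
    gene_start = dict(zip(genes, starts))

    rng_d = _rng(config, 3)
    p_tada = np.empty(len(genes))
    n_dnms = np.zeros(len(genes), dtype=int)
    for i, g in enumerate(genes):
        if g in dnm_set:
            p_tada[i] = rng_d.uniform(1e-6, 0.05)  # strictly below threshold
            n_dnms[i] = int(rng_d.choice([1, 2, 3], p=[0.90, 0.08, 0.02]))
        else:
            p_tada[i] = rng_d.uniform(0.05, 1.0)
    dnm_table = pd.DataFrame({"gene": genes, "p_tada": p_tada, "n_dnms": n_dnms})

    rng_g = _rng(config, 4)
    rows = []
    lo_nl, hi_nl = _PLANTED_NEGLOG10_RANGE
    for g in sorted(cv_set):
        start = gene_start[g]
        pos = int(rng_g.integers(start - 35_000, start + _GENE_BODY + 35_000))
        p = float(10.0 ** (-rng_g.uniform(lo_nl, hi_nl)))
        rows.append({"chrom": "chr1", "pos": pos, "p": p})
    n_decoy = max(100, 3 * config.n_cv_genes)
    chrom_len = int(starts[-1]) + _GENE_SPACING
    decoy_pos = rng_g.integers(0, chrom_len, size=n_decoy)
    decoy_p = rng_g.uniform(5.1e-8, 1.0, size=n_decoy)
    for pos, p in zip(decoy_pos, decoy_p):
        rows.append({"chrom": "chr1", "pos": int(pos), "p": float(p)})
    gwas = pd.DataFrame(rows).sort_values(["pos", "p"], kind="stable")
    gwas.insert(0, "variant_id", [f"v{i:06d}" for i in range(len(gwas))])
    gwas = gwas.reset_index(drop=True)
    return dnm_table, gwas, ann


@dataclass
class SyntheticBundle:
    """All generated artifacts plus the planted ground truth."""

    config: SyntheticConfig
    network: nx.Graph
    panel: ExpressionPanel
    dnm_table: pd.DataFrame
    gwas_table: pd.DataFrame
    annotation: pd.DataFrame
    planted_dnm: frozenset[str]
    planted_cv: frozenset[str]
    planted_module: tuple[str, ...]


def generate_all(config: SyntheticConfig) -> SyntheticBundle:
    network = generate_ppi_network(config)
    genes = sorted(network.nodes)
    dnm_genes, cv_genes = _planted_variant_sets(config, genes)
    module = _planted_module(config, genes)
    panel = generate_expression_panel(network, config)
    dnm_table, gwas, ann = generate_variant_tables(network, config)
    return SyntheticBundle(
        config=config,
        network=network,
        panel=panel,
        dnm_table=dnm_table,
        gwas_table=gwas,
        annotation=ann,
        planted_dnm=frozenset(dnm_genes),
        planted_cv=frozenset(cv_genes),
        planted_module=tuple(module),
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_edge_list(bundle.network, outdir / "ppi_edges.tsv")
    bundle.panel.write(outdir)
    io.write_table(bundle.dnm_table, outdir / "dnm_table.tsv")
    io.write_table(bundle.gwas_table, outdir / "gwas_table.tsv")
    io.write_table(bundle.annotation, outdir / "gene_annotation.tsv")
    truth = {
        "planted_dnm": sorted(bundle.planted_dnm),
        "planted_cv": sorted(bundle.planted_cv),
        "planted_module": list(bundle.planted_module),
    }
    with open(outdir / "planted_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
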