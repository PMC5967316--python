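"""Assembly of DNM and CV gene sets from variant tables.

DNM genes: per-gene TADA-style p < 0.05 AND expressed in at least one
spatiotemporal site. CV genes: at least one genome-wide significant variant
(p < 5e-8) inside the gene body extended by +/-35 kb, AND expressed in at
least one site. CV genes are further split into 7 subgroups of near-equal
size by their -log10(p).

Coordinate convention: gene records are 0-based half-open [start, end); the
variant window test is pos in [start - window, end + window). The window is
therefore inclusive at its upstream edge (start - window) and exclusive at
end + window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A labeled set of gene symbols with optional per-gene p-values."""

    label: str
    genes: frozenset[str]
    per_gene_p: Optional[dict[str, float]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.per_gene_p is not None:
            for g, p in self.per_gene_p.items():
                if not (0.0 < p <= 1.0):
                    raise ValueError(f"p-value for {g} outside (0, 1]: {p}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(self.sorted_genes)

    @property
    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


def _expressed_any(calls: pd.DataFrame) -> pd.Series:
    if calls.shape[1] < 1:
        raise ValueError("expression calls cover no site")
    return calls.any(axis=1)


def select_dnm_genes(
    dnm: pd.DataFrame, calls: pd.DataFrame, p_threshold: float = 0.05
) -> GeneSet:
    """Genes with TADA p strictly below threshold and expressed at >= 1 site."""
    if dnm.empty:
        logger.warning("empty DNM table; returning empty DNM gene set")
        return GeneSet("DNM", frozenset(), {})
    expressed = _expressed_any(calls)
    keep: dict[str, float] = {}
    for gene, p in zip(dnm["gene"], dnm["p_tada"]):
        if p < p_threshold and bool(expressed.get(gene, False)):
            keep[gene] = float(p)
    return GeneSet("DNM", frozenset(keep), keep)


def map_variants_to_genes(
    gwas: pd.DataFrame,
    ann: pd.DataFrame,
    calls: pd.DataFrame,
    p_threshold: float = 5e-8,
    window: int = 35000,
) -> GeneSet:
    """CV genes: >= 1 variant with p < threshold inside [start-w, end+w).

    The per-gene p is the minimum over the gene's significant variants.
    Variants on chromosomes absent from the annotation are ignored (counted
    in the log). Genes must additionally be expressed at >= 1 site.
    """
    expressed = _expressed_any(calls)
    sig = gwas[gwas["p"] < p_threshold]
    per_gene_p: dict[str, float] = {}
    skipped = 0
    by_chrom = {c: sub for c, sub in ann.groupby("chrom")}
    for chrom, variants in sig.groupby("chrom"):
        genes = by_chrom.get(chrom)
        if genes is None:
            skipped += len(variants)
            continue
        lo = genes["start"].to_numpy(dtype=np.int64) - window
        hi = genes["end"].to_numpy(dtype=np.int64) + window
        names = genes["gene"].to_numpy()
        pos = variants["pos"].to_numpy(dtype=np.int64)
        pvals = variants["p"].to_numpy(dtype=float)
        hit = (pos[:, None] >= lo[None, :]) & (pos[:, None] < hi[None, :])
        for vi, gi in zip(*np.nonzero(hit)):
            g = names[gi]
            p = float(pvals[vi])
            if g not in per_gene_p or p < per_gene_p[g]:
                per_gene_p[g] = p
    if skipped:
        logger.info(
            "%d significant variants on chromosomes absent from annotation",
            skipped,
        )
    keep = {
        g: p for g, p in per_gene_p.items() if bool(expressed.get(g, False))
    }
    return GeneSet("CV", frozenset(keep), keep)


def partition_cv_subgroups(cv: GeneSet, k: int = 7) -> list[GeneSet]:
    """Split CV genes into k contiguous -log10(p) subgroups of ~equal size.

    Subgroup 1 holds the least significant genes (smallest -log10(p)),
    subgroup k the most significant. Sizes differ by at most one.
    """
    if cv.per_gene_p is None:
        raise ValueError("CV gene set carries no per-gene p-values")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(cv):
        raise ValueError(f"k={k} exceeds number of genes ({len(cv)})")
    if k == 1:
        return [cv]
    order = sorted(cv.genes, key=lambda g: (-cv.per_gene_p[g], g))
    chunks = np.array_split(np.asarray(order, dtype=object), k)
    return [
        GeneSet(
            f"CV_subgroup_{i + 1}",
            frozenset(chunk),
            {g: cv.per_gene_p[g] for g in chunk},
        )
        for i, chunk in enumerate(chunks)
    ]


def resolve_overlap(
    dnm: GeneSet, cv: GeneSet, mode: str = "exclude_shared"
) -> tuple[GeneSet, GeneSet, frozenset[str]]:
    """Handle genes belonging to both sets.

    ``exclude_shared`` removes the shared genes from both returned sets (used
    for pairwise path/edge analyses); ``union`` returns the sets unchanged
    (the deduplicated union is available via :func:`union_geneset`). The
    shared genes are always reported.
    """
    shared = frozenset(dnm.genes & cv.genes)
    if mode == "union":
        return dnm, cv, shared
    if mode != "exclude_shared":
        raise ValueError(f"unknown overlap mode: {mode!r}")

    def _strip(gs: GeneSet) -> GeneSet:
        genes = gs.genes - shared
        p = (
            {g: gs.per_gene_p[g] for g in genes if g in gs.per_gene_p}
            if gs.per_gene_p is not None
            else None
        )
        return GeneSet(gs.label, genes, p)

    return _strip(dnm), _strip(cv), shared


def union_geneset(dnm: GeneSet, cv: GeneSet, label: str = "seed") -> GeneSet:
    """Deduplicated union of both sets — the subnetwork seed genes."""
    return GeneSet(label, dnm.genes | cv.genes)


def write_gene_sets(sets, path: str | Path) -> None:
    rows = []
    for gs in sets:
        for g in gs.sorted_genes:
            p = gs.per_gene_p.get(g) if gs.per_gene_p else None
            rows.append({"gene": g, "label": gs.label, "p": p})
    pd.DataFrame(rows, columns=["gene", "label", "p"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "label": str})
    out = {}
    for label, sub in df.groupby("label"):
        pmap = {
            g: float(p)
            for g, p in zip(sub["gene"], sub["p"])
            if pd.notna(p)
        }
        out[label] = GeneSet(label, frozenset(sub["gene"]), pmap or None)
    return out
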