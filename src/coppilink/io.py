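"""Readers and writers for the plain-text artifact formats.

Everything is tab-separated text: PPI edge lists (two gene-symbol columns),
weighted edge lists (third ``weight`` column), per-gene variant tables, a
BED-like gene annotation (0-based half-open coordinates) and gene-set tables.
"""
from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

FLOAT_FMT = "%.10g"


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_weighted_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        rows = sorted(
            (min(u, v), max(u, v), d["weight"]) for u, v, d in graph.edges(data=True)
        )
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{FLOAT_FMT % w}\n")


def read_weighted_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    for u, v, w in df.itertuples(index=False, name=None):
        g.add_edge(u, v, weight=float(w))
    return g


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_dnm_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str})


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
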