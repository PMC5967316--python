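"""Co-expression-weighted PPI (CoPPI) construction.

A CoPPI is the PPI network restricted to genes expressed at one site, with
every surviving edge weighted by the absolute Pearson correlation |PCC| of
its endpoints' expression profiles at that site. Edges involving unexpressed
nodes are removed; nodes left isolated by the removal are dropped.
"""
from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io

logger = logging.getLogger(__name__)


def build_coppi(
    ppi: nx.Graph,
    matrix: pd.DataFrame,
    calls: pd.Series,
    site: str,
) -> nx.Graph:
    """Weight PPI edges by |PCC| at one site, keeping expressed genes only.

    ``calls`` is the boolean expression call per gene for this site, computed
    from ``matrix``. PPI genes absent from the matrix are treated as
    unexpressed (logged). Zero-variance genes yield edge weight 0 with a
    logged warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError("co-expression needs >= 3 samples")
    nodes = sorted(ppi.nodes)
    missing = [g for g in nodes if g not in matrix.index]
    if missing:
        logger.info(
            "%d PPI genes absent from the expression matrix at %s; "
            "treated as unexpressed", len(missing), site,
        )
    expressed = [
        g for g in nodes
        if g in matrix.index and bool(calls.get(g, False))
    ]
    expr_set = set(expressed)
    x = matrix.loc[expressed].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc * xc).sum(axis=1))
    idx = {g: i for i, g in enumerate(expressed)}

    edges = sorted(
        (min(u, v), max(u, v))
        for u, v in ppi.edges
        if u in expr_set and v in expr_set and u != v
    )
    g = nx.Graph(site_id=site)
    n_zero_var = 0
    if edges:
        iu = np.fromiter((idx[u] for u, _ in edges), dtype=int, count=len(edges))
        iv = np.fromiter((idx[v] for _, v in edges), dtype=int, count=len(edges))
        dots = np.abs((xc[iu] * xc[iv]).sum(axis=1))
        denom = norms[iu] * norms[iv]
        ok = denom > 0
        n_zero_var = int((~ok).sum())
        weights = np.zeros(len(edges))
        weights[ok] = np.clip(dots[ok] / denom[ok], 0.0, 1.0)
        for (u, v), w in zip(edges, weights):
            g.add_edge(u, v, weight=float(w))
    if n_zero_var:
        logger.warning(
            "%d CoPPI edges at %s involve a zero-variance gene; weight set "
            "to 0", n_zero_var, site,
        )
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def write_coppi(
    coppi: nx.Graph,
    tsv_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    io.write_weighted_edge_list(coppi, tsv_path)
    if graphml_path is not None:
        nx.write_graphml(coppi, graphml_path)
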