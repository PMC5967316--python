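import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coppilink.config import SyntheticConfig
from coppilink import synthetic as syn
from coppilink import expression as expr


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=60,
        n_edges=200,
        n_sites=2,
        samples_per_site=20,
        n_dnm_genes=8,
        n_cv_genes=10,
        n_overlap=2,
        unexpressed_fraction=0.2,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return syn.generate_all(small_config)


@pytest.fixture(scope="session")
def small_calls(small_bundle):
    return expr.panel_calls(small_bundle.panel)


@pytest.fixture()
def toy_matrix() -> pd.DataFrame:
    """4 genes x 3 samples with hand-checkable expression calls."""
    return pd.DataFrame(
        {
            "s1": [0.2, 1.0, 5.0, 0.0],
            "s2": [1.0, 1.0, 2.0, 0.5],
            "s3": [1.7, 1.0, 9.0, 0.9],
        },
        index=["gA", "gB", "gC", "gD"],
    )


def toy_coppi(edges) -> nx.Graph:
    """Weighted graph from (u, v, w) triples."""
    g = nx.Graph(site_id="toy")
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return g


def random_weighted_graph(
    n: int, m: int, rng: np.random.Generator
) -> nx.Graph:
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    h = nx.Graph(site_id="rand")
    for u, v in g.edges:
        h.add_edge(f"n{u:03d}", f"n{v:03d}", weight=float(rng.uniform(0, 1)))
    return h


@pytest.fixture()
def module_panel():
    """One-site panel with a strongly co-expressed planted module."""
    cfg = SyntheticConfig(
        n_genes=80,
        n_edges=240,
        n_sites=1,
        samples_per_site=100,
        coexpr_strength=0.9,
        unexpressed_fraction=0.0,
        n_dnm_genes=1,
        n_cv_genes=1,
        n_overlap=0,
        rng_seed=3,
    )
    net = syn.generate_ppi_network(cfg)
    genes = sorted(net.nodes)
    module = genes[:10]
    cfg = dataclasses.replace(cfg, planted_seed_genes=module)
    panel = syn.generate_expression_panel(net, cfg)
    return net, panel, module
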