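"""Network characterization of gene sets.

Node degree is the number of direct interactors. Betweenness here is the raw
COUNT of shortest paths passing through a node (endpoints excluded, each
unordered pair counted once) — note this is not the conventional fractional
betweenness centrality, which divides by the number of shortest paths per
pair. ``log_betweenness`` is ln(betweenness + 1), keeping leaves finite.

Set-level significance comes from randomization: an empirical p-value is the
exact proportion of random same-size gene sets whose statistic is >= the
observed one (no add-one smoothing, so 0 is reportable as "< 1/n_draws").
The degree-matched variant splits nodes into four rank-based degree
quartiles and draws the observed set's per-quartile composition exactly.
"""
from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, resolve_overlap


def _bfs_all(nodes: list, adj: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from every source (unweighted)."""
    n = len(nodes)
    dist = np.full((n, n), -1, dtype=np.int32)
    sigma = np.zeros((n, n), dtype=np.float64)
    for s in range(n):
        d = dist[s]
        sg = sigma[s]
        d[s] = 0
        sg[s] = 1.0
        q = deque([s])
        while q:
            u = q.popleft()
            du = d[u]
            for v in adj[u]:
                if d[v] < 0:
                    d[v] = du + 1
                    q.append(v)
                if d[v] == du + 1:
                    sg[v] += sg[u]
    return dist, sigma


def path_count_betweenness(graph: nx.Graph) -> dict:
    """Number of shortest paths through each node, over unordered pairs.

    For a node v and pair (s, t) with v internal, the contribution is
    sigma(s,v) * sigma(v,t) when d(s,v) + d(v,t) = d(s,t); summed over all
    unordered pairs s < t, s != v != t. Computed from all-pairs BFS.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    adj = [
        np.fromiter(
            sorted(index[v] for v in graph.neighbors(u)), dtype=np.int64
        )
        for u in nodes
    ]
    dist, sigma = _bfs_all(nodes, adj)
    reach_ok = dist >= 0
    bet = np.zeros(n)
    for s in range(n):
        ds = dist[s]
        reach = reach_ok[s]
        # on_path[v, t]: v lies on a shortest s-t path
        on_path = (ds[:, None] + dist) == ds[None, :]
        on_path &= reach_ok
        on_path &= reach[:, None]
        on_path &= reach[None, :]
        on_path[s, :] = False
        on_path[:, s] = False
        np.fill_diagonal(on_path, False)
        bet += sigma[s] * (on_path * sigma).sum(axis=1)
    bet /= 2.0  # each unordered pair visited from both endpoints
    return dict(zip(nodes, bet))


def node_metrics(graph: nx.Graph, betweenness: bool = True) -> pd.DataFrame:
    """Per-node degree, path-count betweenness and ln(betweenness + 1)."""
    nodes = sorted(graph.nodes)
    out = pd.DataFrame(index=pd.Index(nodes, name="gene"))
    out["degree"] = [graph.degree(g) for g in nodes]
    if betweenness:
        bet = path_count_betweenness(graph)
        out["betweenness"] = [bet[g] for g in nodes]
        out["log_betweenness"] = np.log(out["betweenness"].to_numpy() + 1.0)
    return out


def shortest_path_profile(
    set_a: Iterable[str], set_b: Iterable[str], graph: nx.Graph
) -> pd.DataFrame:
    """Distribution of shortest-path lengths over cross (or within) pairs.

    Within-set mode (identical sets) counts unordered pairs once; cross mode
    requires disjoint sets. Disconnected pairs fall in an ``unreachable``
    bin. The length-1 bin is the direct-interaction proportion.
    """
    nodes = set(graph.nodes)
    a = sorted(set(set_a) & nodes)
    b_set = set(set_b) & nodes
    within = set(set_a) == set(set_b)
    if not within and (set(a) & b_set):
        raise ValueError(
            "cross-set profile requires disjoint sets; resolve overlap first"
        )
    counts: Counter = Counter()
    for u in a:
        dist = nx.single_source_shortest_path_length(graph, u)
        targets = (v for v in b_set if v > u) if within else iter(b_set)
        for v in targets:
            d = dist.get(v)
            counts[d if d is not None else "unreachable"] += 1
    total = sum(counts.values())
    keys = sorted((k for k in counts if k != "unreachable"))
    if "unreachable" in counts:
        keys.append("unreachable")
    return pd.DataFrame(
        {
            "length": keys,
            "n_pairs": [counts[k] for k in keys],
            "proportion": [counts[k] / total if total else 0.0 for k in keys],
        }
    )


@dataclass
class RandomizationResult:
    observed: float
    null: np.ndarray
    p: float
    n_draws: int
    rng_seed: int
    matching: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.p <= 1.0
        assert len(self.null) == self.n_draws


def degree_quartiles(graph: nx.Graph) -> list[list]:
    """Four near-equal node groups by degree rank (stable node-id ties)."""
    order = sorted(graph.nodes, key=lambda g: (graph.degree(g), g))
    return [list(part) for part in np.array_split(np.asarray(order, object), 4)]


def degree_matched_sample(
    quartiles: Sequence[Sequence],
    observed_counts: Sequence[int],
    rng: np.random.Generator,
) -> list:
    """One random set matching the observed per-quartile composition."""
    pick: list = []
    for part, k in zip(quartiles, observed_counts):
        if k > len(part):
            raise ValueError(
                f"degree quartile has {len(part)} nodes but {k} are required"
            )
        if k:
            pick.extend(rng.choice(np.asarray(part, object), size=k,
                                   replace=False))
    return pick


def empirical_p(
    stat: Callable[[Sequence, nx.Graph], float],
    observed_set: Iterable[str],
    graph: nx.Graph,
    n_draws: int = 10000,
    matching: str = "plain",
    rng_seed: int = 0,
) -> RandomizationResult:
    """Empirical p = proportion of random sets with statistic >= observed.

    ``plain`` draws |set| nodes uniformly without replacement;
    ``degree_quartile`` matches the observed set's per-degree-quartile
    counts exactly in every draw.
    """
    observed = sorted(set(observed_set))
    nodes = np.asarray(sorted(graph.nodes), dtype=object)
    if set(observed) - set(nodes):
        raise ValueError("observed set contains nodes absent from the network")
    if matching not in ("plain", "degree_quartile"):
        raise ValueError(f"unknown matching mode: {matching!r}")
    rng = np.random.default_rng(rng_seed)
    obs_val = float(stat(observed, graph))
    null = np.empty(n_draws)
    if matching == "plain":
        for i in range(n_draws):
            pick = rng.choice(nodes, size=len(observed), replace=False)
            null[i] = stat(list(pick), graph)
    else:
        quartiles = degree_quartiles(graph)
        qsets = [set(q) for q in quartiles]
        counts = [sum(1 for g in observed if g in qs) for qs in qsets]
        for i in range(n_draws):
            pick = degree_matched_sample(quartiles, counts, rng)
            null[i] = stat(pick, graph)
    p = float(np.mean(null >= obs_val))
    return RandomizationResult(
        observed=obs_val, null=null, p=p, n_draws=n_draws,
        rng_seed=rng_seed, matching=matching,
    )


def empirical_p_pair(
    stat: Callable[[Sequence, Sequence, nx.Graph], float],
    set_a: Iterable[str],
    set_b: Iterable[str],
    graph: nx.Graph,
    n_draws: int = 10000,
    matching: str = "plain",
    rng_seed: int = 0,
) -> RandomizationResult:
    """Two-set randomization (e.g., DNM-CV cross edge counts).

    Both random sets are drawn disjointly; in degree-matched mode each set
    reproduces its own per-quartile composition.
    """
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    if set(a) & set(b):
        raise ValueError("sets must be disjoint; resolve overlap first")
    nodes = np.asarray(sorted(graph.nodes), dtype=object)
    rng = np.random.default_rng(rng_seed)
    obs_val = float(stat(a, b, graph))
    null = np.empty(n_draws)
    if matching == "plain":
        for i in range(n_draws):
            pick = rng.choice(nodes, size=len(a) + len(b), replace=False)
            null[i] = stat(list(pick[: len(a)]), list(pick[len(a):]), graph)
    elif matching == "degree_quartile":
        quartiles = degree_quartiles(graph)
        qsets = [set(q) for q in quartiles]
        counts_a = [sum(1 for g in a if g in qs) for qs in qsets]
        counts_b = [sum(1 for g in b if g in qs) for qs in qsets]
        for i in range(n_draws):
            pa = degree_matched_sample(quartiles, counts_a, rng)
            taken = set(pa)
            rest = [
                [g for g in q if g not in taken] for q in quartiles
            ]
            pb = degree_matched_sample(rest, counts_b, rng)
            null[i] = stat(pa, pb, graph)
    else:
        raise ValueError(f"unknown matching mode: {matching!r}")
    p = float(np.mean(null >= obs_val))
    return RandomizationResult(
        observed=obs_val, null=null, p=p, n_draws=n_draws,
        rng_seed=rng_seed, matching=matching,
    )


# ---------------------------------------------------------------------------
# set-level statistic helpers

def within_set_edge_count(genes: Sequence, graph: nx.Graph) -> float:
    """Number of network edges with both endpoints in the set."""
    s = set(genes)
    return float(sum(1 for u, v in graph.edges(s) if u in s and v in s))


def cross_edge_count(a: Sequence, b: Sequence, graph: nx.Graph) -> float:
    """Number of edges with one endpoint in each (disjoint) set."""
    sa, sb = set(a), set(b)
    n = 0
    for u in sa:
        if u in graph:
            n += sum(1 for v in graph.neighbors(u) if v in sb)
    return float(n)


def mean_degree(genes: Sequence, graph: nx.Graph) -> float:
    return float(np.mean([graph.degree(g) for g in genes]))


def make_metric_stat(metrics: pd.DataFrame, column: str) -> Callable:
    """Set-level mean of a precomputed node metric (fast lookup)."""
    values = metrics[column].to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(metrics.index)}

    def stat(genes: Sequence, graph: nx.Graph) -> float:
        rows = np.fromiter((index[g] for g in genes), dtype=int,
                           count=len(genes))
        return float(values[rows].mean())

    return stat


# ---------------------------------------------------------------------------
# group tests

def group_comparison(
    metrics: pd.DataFrame,
    sets: Sequence[GeneSet],
    metric_cols: Sequence[str] = ("degree", "log_betweenness"),
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests: each set vs all other genes."""
    rows = []
    all_genes = set(metrics.index)
    for gs in sets:
        members = sorted(gs.genes & all_genes)
        others = sorted(all_genes - gs.genes)
        if not members or not others:
            raise ValueError(f"set {gs.label!r} leaves an empty group")
        for col in metric_cols:
            a = metrics.loc[members, col].to_numpy(dtype=float)
            b = metrics.loc[others, col].to_numpy(dtype=float)
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "set": gs.label,
                    "metric": col,
                    "n_set": len(a),
                    "n_other": len(b),
                    "mean_set": float(a.mean()),
                    "mean_other": float(b.mean()),
                    "statistic": float(u),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def _edge_weights(graph: nx.Graph) -> dict[tuple, float]:
    return {
        (min(u, v), max(u, v)): d["weight"]
        for u, v, d in graph.edges(data=True)
    }


def edge_group_coexpression_test(
    coppi: nx.Graph,
    edge_groups: Mapping[str, tuple[Iterable[str], Iterable[str]]],
) -> pd.DataFrame:
    """t-tests of edge weights: group edges vs all other edges, one site.

    ``edge_groups`` maps a group name to a pair of gene sets; a group edge
    has one endpoint in each set (both in the same set for within-group
    tests). Raw p only — use :func:`edge_coexpression_tests` for the
    Bonferroni correction across sites and groups.
    """
    weights = _edge_weights(coppi)
    all_edges = set(weights)
    rows = []
    for name, (ga, gb) in edge_groups.items():
        sa, sb = set(ga), set(gb)
        group = {
            e for e in all_edges
            if (e[0] in sa and e[1] in sb) or (e[0] in sb and e[1] in sa)
        }
        other = all_edges - group
        if not group or not other:
            rows.append(
                {"group": name, "n_group": len(group), "n_other": len(other),
                 "mean_group": np.nan, "mean_other": np.nan,
                 "t": np.nan, "p": np.nan}
            )
            continue
        wg = np.asarray([weights[e] for e in sorted(group)])
        wo = np.asarray([weights[e] for e in sorted(other)])
        if len(wg) < 2 or len(wo) < 2:
            t = p = np.nan
        else:
            t, p = stats.ttest_ind(wg, wo, equal_var=False)
        rows.append(
            {"group": name, "n_group": len(wg), "n_other": len(wo),
             "mean_group": float(wg.mean()), "mean_other": float(wo.mean()),
             "t": t, "p": p}
        )
    return pd.DataFrame(rows)


def edge_coexpression_tests(
    coppis: Mapping[str, nx.Graph],
    dnm: GeneSet,
    cv: GeneSet,
) -> pd.DataFrame:
    """Within-DNM / within-CV / DNM-CV-cross edge weight tests, all sites.

    Shared genes are excluded from both sets first; Bonferroni correction is
    applied across the full (site, group) grid.
    """
    d, c, _ = resolve_overlap(dnm, cv, mode="exclude_shared")
    groups = {
        "within_DNM": (d.genes, d.genes),
        "within_CV": (c.genes, c.genes),
        "DNM_CV_cross": (d.genes, c.genes),
    }
    tables = []
    for site, coppi in coppis.items():
        tab = edge_group_coexpression_test(coppi, groups)
        tab.insert(0, "site", site)
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    ok = table["p"].notna()
    table["p_bonferroni"] = np.nan
    if ok.any():
        table.loc[ok, "p_bonferroni"] = multipletests(
            table.loc[ok, "p"].to_numpy(), method="bonferroni"
        )[1]
    return table
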