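"""Topological position of DC genes relative to key drivers.

Two statistics locate a gene with respect to an externally supplied set
of key-driver (causal) genes:

* **minimum shortest path (MSP)** — the smallest unweighted graph
  distance from the gene to any key driver;
* **bipartite betweenness centrality (BBC)** — Brandes-style shortest-path
  flow restricted to ordered (source, target) pairs with sources = key
  drivers and targets = peripheral genes (degree-1 nodes); each interior
  vertex v accumulates sigma_st(v)/sigma_st, endpoints receive no credit.

Group comparisons (DC genes versus the rest) use the Mann–Whitney
rank-sum test and a label-permutation test on the group mean difference.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "min_shortest_path_to_set",
    "msp_table",
    "bipartite_betweenness",
    "rank_sum_test",
    "permutation_test_mean_diff",
    "topology_table",
    "compare_dc_topology",
]

logger = logging.getLogger(__name__)


def min_shortest_path_to_set(
    graph: nx.Graph, gene: str, drivers: Iterable[str]
) -> int | None:
    """Smallest unweighted distance from ``gene`` to any reachable driver.

    Returns None when no driver is reachable; a gene that is itself a
    driver has distance 0.  A gene absent from the network is an error.
    """
    drivers = set(drivers)
    if not drivers:
        raise ValueError("drivers must be nonempty")
    if gene not in graph:
        raise ValueError(f"gene {gene!r} not in network")
    if gene in drivers:
        return 0
    lengths = nx.single_source_shortest_path_length(graph, gene)
    hits = [d for g, d in lengths.items() if g in drivers]
    return min(hits) if hits else None


def msp_table(graph: nx.Graph, drivers: Iterable[str]) -> dict[str, int | None]:
    """MSP for every node at once via multi-source breadth-first search."""
    drivers = {d for d in drivers if d in graph}
    out: dict[str, int | None] = {g: None for g in graph.nodes}
    if not drivers:
        return out
    dist = {d: 0 for d in drivers}
    queue = deque(drivers)
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    out.update(dist)
    return out


def bipartite_betweenness(
    graph: nx.Graph, sources: Iterable[str], targets: Iterable[str]
) -> dict[str, float]:
    """Shortest-path betweenness restricted to source -> target pairs.

    For every ordered pair (s, t) with s in sources, t in targets and
    s != t, each vertex v interior to the s–t shortest paths accumulates
    the fraction sigma_st(v)/sigma_st of those paths passing through it
    (Brandes accumulation with fractional path counting).  Unreachable
    pairs contribute nothing; an empty source or target set yields an
    all-zero map with a warning.
    """
    sources = [s for s in sources if s in graph]
    target_set = {t for t in targets if t in graph}
    bbc: dict[str, float] = {v: 0.0 for v in graph.nodes}
    if not sources or not target_set:
        logger.warning("empty source or target set; bipartite betweenness is all zero")
        return bbc

    for s in sources:
        # single-source BFS with path counting (Brandes)
        sigma: dict[str, float] = {s: 1.0}
        dist: dict[str, int] = {s: 0}
        preds: dict[str, list[str]] = {s: []}
        order: list[str] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0.0
                    preds[v] = []
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        # dependency accumulation restricted to targets
        delta: dict[str, float] = {v: 0.0 for v in order}
        for w in reversed(order):
            coeff = delta[w] + (1.0 if (w in target_set and w != s) else 0.0)
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * coeff
            if w != s:
                bbc[w] += delta[w]
        bbc[s] += 0.0  # sources as interior vertices of *other* sources' pairs only
    return bbc


def rank_sum_test(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Mann–Whitney U with the tie-corrected normal approximation.

    Returns (U for the first sample, two-sided p).  Two identical
    constant samples (every value tied) return p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return float(x.size * y.size / 2.0), 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def permutation_test_mean_diff(
    values: Mapping[str, float],
    group_labels: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation test for mean(dc) - mean(other).

    Labels are shuffled uniformly over all eligible genes; the p-value is
    (1 + #{|permuted stat| >= |observed|}) / (n_perm + 1), reproducible
    for a fixed seed.
    """
    genes = sorted(values)
    vals = np.array([values[g] for g in genes], dtype=float)
    labels = np.array([group_labels[g] for g in genes])
    dc_mask = labels == "dc"
    n_dc = int(dc_mask.sum())
    if n_dc == 0 or n_dc == len(genes):
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = vals[dc_mask].mean() - vals[~dc_mask].mean()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(genes))[:n_dc]
        mask = np.zeros(len(genes), dtype=bool)
        mask[perm] = True
        stat = vals[mask].mean() - vals[~mask].mean()
        if abs(stat) >= abs(observed) - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def topology_table(
    network, drivers: Iterable[str], dc: Iterable[str]
) -> pd.DataFrame:
    """Per-gene topology annotation for a condition network.

    Columns: gene, is_key_driver, is_peripheral (degree exactly 1),
    is_dc, degree, msp (NaN if no driver reachable) and bbc (flow from
    key drivers to peripheral genes).
    """
    graph = network.graph if hasattr(network, "graph") else network
    drivers = {d for d in drivers if d in graph}
    dc = set(dc)
    msp = msp_table(graph, drivers)
    peripheral = {g for g in graph.nodes if graph.degree(g) == 1}
    bbc = bipartite_betweenness(graph, drivers, peripheral)
    rows = [
        {
            "gene": g,
            "is_key_driver": g in drivers,
            "is_peripheral": g in peripheral,
            "is_dc": g in dc,
            "degree": graph.degree(g),
            "msp": float("nan") if msp[g] is None else msp[g],
            "bbc": bbc[g],
        }
        for g in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows)


def compare_dc_topology(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Group statistics contrasting DC genes with the rest of the network.

    MSP: rank-sum and permutation tests over all non-driver genes with a
    reachable driver.  BBC: rank-sum test over non-driver, non-peripheral
    genes (the published comparison set).  Genes with undefined MSP are
    excluded, with counts reported.
    """
    out: dict = {}
    msp_tab = table[~table.is_key_driver & table.msp.notna()]
    out["n_msp_excluded_unreachable"] = int(
        (~table.is_key_driver & table.msp.isna()).sum()
    )
    dc_msp = msp_tab.loc[msp_tab.is_dc, "msp"]
    other_msp = msp_tab.loc[~msp_tab.is_dc, "msp"]
    if len(dc_msp) and len(other_msp):
        u, p = rank_sum_test(dc_msp, other_msp)
        out["msp_rank_sum_U"], out["msp_rank_sum_p"] = u, p
        out["msp_permutation_p"] = permutation_test_mean_diff(
            dict(zip(msp_tab.gene, msp_tab.msp)),
            {g: ("dc" if d else "other") for g, d in zip(msp_tab.gene, msp_tab.is_dc)},
            n_perm=n_perm,
            seed=seed,
        )
    bbc_tab = table[~table.is_key_driver & ~table.is_peripheral]
    dc_bbc = bbc_tab.loc[bbc_tab.is_dc, "bbc"]
    other_bbc = bbc_tab.loc[~bbc_tab.is_dc, "bbc"]
    if len(dc_bbc) and len(other_bbc):
        u, p = rank_sum_test(dc_bbc, other_bbc)
        out["bbc_rank_sum_U"], out["bbc_rank_sum_p"] = u, p
    return out
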