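"""Condition-specific co-expression networks over DEG nodes.

A network for one condition is an undirected simple graph whose nodes are
the differentially expressed genes and whose edges are gene pairs with a
significant, direction-consistent Pearson correlation across datasets,
after Fisher meta-analysis, BH FDR control and the PUC sign-concordance
filter (correlation sign must match the product of the two genes'
differential-expression directions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset
from .meta import meta_screen

__all__ = [
    "PearsonResult",
    "pearson_with_p",
    "pairwise_pearson",
    "condition_pair_stats",
    "puc_filter",
    "CoexpressionNetwork",
    "build_network",
]

logger = logging.getLogger(__name__)

MIN_CORR_SAMPLES = 4  # Fisher z needs n - 3 > 0


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int
    testable: bool


def _corr_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2.0) / np.maximum(1.0 - r * r, 0.0))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2.0, 1.0))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(n < MIN_CORR_SAMPLES, np.nan, p)
    return p


def pearson_with_p(x: Iterable[float], y: Iterable[float]) -> PearsonResult:
    """Sample Pearson correlation with its t-based two-sided p-value.

    Complete-case samples only; fewer than four complete pairs or a
    constant vector yields an untestable result (NaN statistics, flag
    False) rather than an exception.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < MIN_CORR_SAMPLES:
        return PearsonResult(float("nan"), float("nan"), n, False)
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return PearsonResult(float("nan"), float("nan"), n, False)
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = min(1.0, max(-1.0, r))
    p = float(_corr_pvalue(r, n))
    return PearsonResult(r, p, n, True)


def pairwise_pearson(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Pearson correlation for a gene-by-sample matrix.

    Returns (R, P, N): correlation, two-sided p and complete-case count
    matrices (genes x genes).  Rows that are constant or have fewer than
    four complete cases with their partner are untestable (NaN).  The fast
    path requires a fully observed matrix; missing values fall back to a
    pairwise complete-case loop.
    """
    X = np.asarray(X, dtype=float)
    g, n = X.shape
    if not np.isnan(X).any():
        if n < MIN_CORR_SAMPLES:
            shape = (g, g)
            return np.full(shape, np.nan), np.full(shape, np.nan), np.full(shape, n)
        sd = X.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.corrcoef(X)
        R = np.clip(R, -1.0, 1.0)
        R[sd == 0.0, :] = np.nan
        R[:, sd == 0.0] = np.nan
        N = np.full((g, g), n)
        P = _corr_pvalue(R, N)
        np.fill_diagonal(R, 1.0)
        np.fill_diagonal(P, 0.0)
        return R, P, N

    R = np.full((g, g), np.nan)
    P = np.full((g, g), np.nan)
    N = np.zeros((g, g), dtype=int)
    finite = np.isfinite(X)
    for i in range(g):
        R[i, i], P[i, i], N[i, i] = 1.0, 0.0, int(finite[i].sum())
        for j in range(i + 1, g):
            res = pearson_with_p(X[i], X[j])
            N[i, j] = N[j, i] = res.n
            if res.testable:
                R[i, j] = R[j, i] = res.r
                P[i, j] = P[j, i] = res.p
    return R, P, N


def condition_pair_stats(
    datasets: list[ExpressionDataset], genes: list[str], condition: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-dataset pairwise correlation evidence for one condition.

    Returns condensed upper-triangle arrays ``R, P, N`` of shape
    (m_datasets, n_pairs) plus the (iu, ju) index pair defining pair order.
    """
    g = len(genes)
    iu, ju = np.triu_indices(g, k=1)
    R = np.full((len(datasets), iu.size), np.nan)
    P = np.full((len(datasets), iu.size), np.nan)
    N = np.zeros((len(datasets), iu.size), dtype=int)
    for d, ds in enumerate(datasets):
        X = ds.condition_matrix(condition, genes=genes)
        if X.shape[1] < MIN_CORR_SAMPLES:
            logger.warning(
                "dataset %s has <%d samples in condition %s; skipped for correlation",
                ds.dataset_id, MIN_CORR_SAMPLES, condition,
            )
            continue
        Rm, Pm, Nm = pairwise_pearson(X)
        R[d], P[d], N[d] = Rm[iu, ju], Pm[iu, ju], Nm[iu, ju]
    return R, P, N, np.vstack([iu, ju])


def puc_filter(sign_r: int, dir_i: str, dir_j: str) -> bool:
    """Sign-concordance (PUC) edge filter.

    A correlation is "expected" when its sign equals the product of the two
    genes' differential-expression directions: positive for UP/UP or DN/DN
    pairs, negative for discordant pairs.  Unexpected correlations are
    discarded from the networks.
    """
    if sign_r not in (-1, 1):
        raise ValueError("sign_r must be -1 or +1")
    for d in (dir_i, dir_j):
        if d not in ("UP", "DN"):
            raise ValueError(f"direction must be 'UP' or 'DN', got {d!r}")
    expected = 1 if dir_i == dir_j else -1
    return sign_r == expected


@dataclass
class CoexpressionNetwork:
    """Undirected simple graph over DEG nodes for one condition.

    Edges carry ``sign`` (consensus correlation sign), ``combined_p`` and
    ``q`` attributes.
    """

    condition: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def edge_sign(self, u: str, v: str) -> int:
        return int(self.graph.edges[u, v]["sign"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": min(u, v),
                "target": max(u, v),
                "sign": int(d.get("sign", 0)),
                "combined_p": d.get("combined_p", float("nan")),
                "q": d.get("q", float("nan")),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        out = pd.DataFrame(rows, columns=["source", "target", "sign", "combined_p", "q"])
        return out.sort_values(["source", "target"]).reset_index(drop=True)


def build_network(
    datasets: list[ExpressionDataset],
    deg_directions: Mapping[str, str],
    condition: str,
    *,
    p_corr: float = 0.20,
    q_corr: float = 0.025,
    k_required: int | None = None,
    puc: bool = True,
    veto: bool = False,
) -> CoexpressionNetwork:
    """Infer the co-expression network for one condition.

    For every unordered pair of DEG nodes: per-dataset Pearson r and p over
    that condition's samples, direction filter on sign(r) at ``k_required``
    (with per-dataset ``p < p_corr`` support in the agreeing datasets),
    Fisher combination, BH FDR at ``q_corr``, and finally the PUC filter.
    ``deg_directions`` maps each node to its regulation ('UP'/'DN').
    """
    genes = sorted(deg_directions)
    if k_required is None:
        k_required = len(datasets)
    net = CoexpressionNetwork(condition=condition)
    net.graph.add_nodes_from(genes)
    if len(genes) < 2:
        return net
    R, P, N, idx = condition_pair_stats(datasets, genes, condition)
    if not np.isfinite(P).any():
        logger.warning("no testable pairs in condition %s; empty network", condition)
        return net
    signs = np.sign(np.where(np.isfinite(R), R, 0.0))
    res = meta_screen(
        P, signs, k_required=k_required, p_within=p_corr, q_threshold=q_corr, veto=veto
    )
    accepted = res.accepted
    iu, ju = idx
    dirs = [deg_directions[g] for g in genes]
    for k in np.flatnonzero(accepted):
        i, j = int(iu[k]), int(ju[k])
        sign = int(res.consensus[k])
        if puc and not puc_filter(sign, dirs[i], dirs[j]):
            continue
        net.graph.add_edge(
            genes[i],
            genes[j],
            sign=sign,
            combined_p=float(res.combined_p[k]),
            q=float(res.q[k]),
        )
    return net
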