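"""Local partial correlation (LPC) networks.

When variables outnumber samples the full precision matrix is not
estimable, so the partial correlation of each significantly correlated
pair is computed from the inverse of the *local* correlation sub-matrix:
the pair plus every gene significantly correlated with either member
(genes correlated only with the neighbours are excluded).  If the
neighbourhood still exceeds the sample count n, only the floor(n/2)
neighbours with the strongest correlation to either pair member are
retained.  The pair's p-value uses the same sub-matrix: a t statistic
with n - k - 2 degrees of freedom, k being the conditioning-set size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .io import ExpressionDataset
from .meta import meta_screen
from .networks import (
    CoexpressionNetwork,
    MIN_CORR_SAMPLES,
    pairwise_pearson,
    puc_filter,
)

__all__ = [
    "LPCEdge",
    "neighborhood",
    "cap_neighborhood",
    "local_partial_corr",
    "build_lpc_network",
]

logger = logging.getLogger(__name__)

RIDGE = 1e-8  # diagonal ridge applied to singular sub-matrices
MIN_LPC_SAMPLES = 6  # smallest n for which the capped df n - n/2 - 2 stays >= 1


@dataclass(frozen=True)
class LPCEdge:
    """A pair's local-partial-correlation evidence in one dataset."""

    gene_i: str
    gene_j: str
    neighborhood: frozenset
    k: int
    partial_r: float
    p: float
    n: int


def neighborhood(network, pair: tuple[str, str]) -> set[str]:
    """Conditioning candidates for a pair: genes adjacent to either member.

    ``network`` may be a :class:`CoexpressionNetwork` or a plain
    ``networkx.Graph`` of screened correlations.  Genes correlated only
    with the neighbours but with neither pair member are excluded.
    """
    graph = network.graph if isinstance(network, CoexpressionNetwork) else network
    i, j = pair
    nbrs = set(graph.neighbors(i)) | set(graph.neighbors(j))
    return nbrs - {i, j}


def cap_neighborhood(
    neighbors: set[str],
    corr_to_pair: Mapping[str, tuple[float, float]],
    n: int,
    trigger: int | None = None,
) -> set[str]:
    """Cap an oversized neighbourhood at floor(n/2) genes.

    Triggered when the neighbour count exceeds ``trigger`` (default: the
    sample count n); the neighbours are ranked by max(|r to gene_i|,
    |r to gene_j|) decreasingly and the first floor(n/2) retained.  Ties
    at the cut break by lexicographic gene id (deterministic).
    """
    if n < MIN_CORR_SAMPLES:
        raise ValueError("cap_neighborhood requires n >= 4")
    if trigger is None:
        trigger = n
    if len(neighbors) <= trigger:
        return set(neighbors)
    ranked = sorted(
        neighbors,
        key=lambda g: (-max(abs(corr_to_pair[g][0]), abs(corr_to_pair[g][1])), g),
    )
    return set(ranked[: n // 2])


def local_partial_corr(
    corr_submatrix: np.ndarray,
    n: int,
    pair_indices: tuple[int, int] = (0, 1),
) -> tuple[float, float]:
    """Partial correlation of a pair given its local sub-matrix.

    Inverts the correlation sub-matrix (pair plus conditioning genes) and
    returns ``(-Omega_ij / sqrt(Omega_ii * Omega_jj), p)`` with the p-value
    from a t statistic on n - k - 2 degrees of freedom.  A singular
    sub-matrix gets a small diagonal ridge with a logged warning.
    """
    c = np.asarray(corr_submatrix, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("corr_submatrix must be square")
    k = c.shape[0] - 2
    df = n - k - 2
    if df < 1:
        raise ValueError(f"n - k - 2 must be >= 1 (n={n}, k={k})")
    try:
        omega = np.linalg.inv(c)
    except np.linalg.LinAlgError:
        logger.warning("singular local sub-matrix; applying ridge %.0e", RIDGE)
        omega = np.linalg.inv(c + RIDGE * np.eye(c.shape[0]))
    i, j = pair_indices
    pr = float(-omega[i, j] / np.sqrt(omega[i, i] * omega[j, j]))
    pr = min(1.0, max(-1.0, pr))
    if abs(pr) == 1.0:
        return pr, 0.0
    t = pr * np.sqrt(df / (1.0 - pr * pr))
    return pr, float(2.0 * stats.t.sf(abs(t), df))


def _dataset_lpc(
    X: np.ndarray, genes: list[str], p_screen: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair local partial correlations for one dataset/condition.

    Returns condensed (partial_r, p) vectors over the upper triangle; pairs
    failing the Pearson screen stay NaN (untestable for this dataset).
    """
    g = len(genes)
    n = X.shape[1]
    R, P, _ = pairwise_pearson(X)
    iu, ju = np.triu_indices(g, k=1)
    screened = np.isfinite(P[iu, ju]) & (P[iu, ju] < p_screen)

    graph = nx.Graph()
    graph.add_nodes_from(range(g))
    for k in np.flatnonzero(screened):
        graph.add_edge(int(iu[k]), int(ju[k]))

    pr = np.full(iu.size, np.nan)
    pp = np.full(iu.size, np.nan)
    names = {idx: gene for idx, gene in enumerate(genes)}
    # the t test needs df = n - k - 2 >= 1, so the cap must also fire for
    # neighbourhoods between n - 3 and n that the size-vs-n rule would keep
    trigger = min(n, n - 3)
    for k in np.flatnonzero(screened):
        i, j = int(iu[k]), int(ju[k])
        nbrs = neighborhood(graph, (i, j))
        if len(nbrs) > trigger:
            # rank on gene id for the deterministic tie-break, as documented
            named = {names[v]: (R[v, i], R[v, j]) for v in nbrs}
            kept_names = cap_neighborhood(set(named), named, n, trigger=trigger)
            nbrs = {v for v in nbrs if names[v] in kept_names}
        cond = sorted(nbrs)
        sub_idx = [i, j] + cond
        sub = R[np.ix_(sub_idx, sub_idx)]
        pr[k], pp[k] = local_partial_corr(sub, n)
    return pr, pp


def build_lpc_network(
    datasets: list[ExpressionDataset],
    deg_directions: Mapping[str, str],
    condition: str,
    *,
    p_lpc_screen: float = 0.40,
    q_lpc: float = 0.05,
    k_required: int | None = None,
    puc: bool = True,
) -> CoexpressionNetwork:
    """Infer the local-partial-correlation network for one condition.

    Per dataset: Pearson screen at ``p_lpc_screen``, neighbourhood
    extraction, n/2 cap, local sub-matrix inversion.  Across datasets:
    direction filter on the sign of the partial correlation, Fisher
    combination over agreeing datasets, BH FDR at ``q_lpc`` and the PUC
    filter.  Datasets with fewer than 6 samples in the condition are
    skipped with a warning.
    """
    genes = sorted(deg_directions)
    if k_required is None:
        k_required = len(datasets)
    net = CoexpressionNetwork(condition=condition)
    net.graph.add_nodes_from(genes)
    if len(genes) < 2:
        return net

    iu, ju = np.triu_indices(len(genes), k=1)
    PR = np.full((len(datasets), iu.size), np.nan)
    PP = np.full((len(datasets), iu.size), np.nan)
    for d, ds in enumerate(datasets):
        X = ds.condition_matrix(condition, genes=genes)
        X = X[:, ~np.isnan(X).all(axis=0)] if np.isnan(X).any() else X
        if X.shape[1] < MIN_LPC_SAMPLES:
            logger.warning(
                "dataset %s has <%d samples in condition %s; skipped for LPC",
                ds.dataset_id, MIN_LPC_SAMPLES, condition,
            )
            continue
        PR[d], PP[d] = _dataset_lpc(X, genes, p_lpc_screen)

    if not np.isfinite(PP).any():
        logger.warning("no testable pairs for LPC in condition %s; empty network", condition)
        return net

    signs = np.sign(np.where(np.isfinite(PR), PR, 0.0))
    res = meta_screen(
        PP, signs, k_required=k_required, p_within=p_lpc_screen, q_threshold=q_lpc
    )
    dirs = {g: deg_directions[g] for g in genes}
    for k in np.flatnonzero(res.accepted):
        i, j = genes[int(iu[k])], genes[int(ju[k])]
        sign = int(res.consensus[k])
        if puc and not puc_filter(sign, dirs[i], dirs[j]):
            continue
        net.graph.add_edge(
            i, j, sign=sign, combined_p=float(res.combined_p[k]), q=float(res.q[k])
        )
    return net
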