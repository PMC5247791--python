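"""Differentially correlated pairs (DCPs) between two conditions.

A candidate pair must be nominally correlated (per-dataset p below a
screen threshold, direction-consistent) in at least one condition.  The
per-dataset change in correlation is tested with the Fisher z two-sample
statistic, the change signs pass the direction filter, agreeing p-values
are Fisher-combined and BH FDR is applied.  Finally, only pairs that are
an edge in exactly one of the two condition networks are kept: a *gain*
is an edge present only in the perturbed (B) network, a *loss* an edge
present only in the reference (A) network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset
from .meta import MetaSummary, meta_screen
from .networks import CoexpressionNetwork, condition_pair_stats

__all__ = ["fisher_z", "diff_corr_test", "DCPRecord", "call_dcps", "dcp_table", "dc_genes"]

logger = logging.getLogger(__name__)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = atanh(r) = 0.5*ln((1+r)/(1-r))."""
    r = float(r)
    if not abs(r) < 1.0:
        raise ValueError("fisher_z requires |r| < 1")
    return float(np.arctanh(r))


def diff_corr_test(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided test for a difference between two independent correlations.

    Z = (z(r1) - z(r2)) / sqrt(1/(n1-3) + 1/(n2-3)) referred to a standard
    normal.  Preconditions (n >= 4, |r| < 1) violated -> NaN (untestable),
    not an exception.
    """
    if n1 < 4 or n2 < 4 or not (abs(r1) < 1.0 and abs(r2) < 1.0):
        return float("nan")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class DCPRecord:
    """A differentially correlated gene pair with its evidence trail."""

    gene_i: str
    gene_j: str
    r_A: tuple          # per-dataset Pearson r in condition A
    r_B: tuple          # per-dataset Pearson r in condition B
    per_dataset_diff_p: tuple
    meta: MetaSummary
    change_direction: str  # 'gain' or 'loss'
    host_network: str      # 'B' for gains, 'A' for losses
    sign_in_host: int      # consensus correlation sign in the hosting network
    regulation_i: str      # 'UP'/'DN'
    regulation_j: str


def _condition_support(
    P: np.ndarray, R: np.ndarray, k_required: int, p_screen: float
) -> np.ndarray:
    """Pairs nominally correlated (direction-consistent) in one condition."""
    signs = np.sign(np.where(np.isfinite(R), R, 0.0))
    res = meta_screen(
        P, signs, k_required=k_required, p_within=p_screen, q_threshold=1.0
    )
    return res.pass_direction & (res.n_support >= k_required)


def call_dcps(
    datasets: list[ExpressionDataset],
    network_A: CoexpressionNetwork,
    network_B: CoexpressionNetwork,
    deg_directions: dict[str, str],
    *,
    p_screen: float = 0.20,
    p_diff: float = 0.10,
    q_diff: float = 0.02,
    k_required: int | None = None,
    with_counts: bool = False,
) -> list[DCPRecord] | tuple[list[DCPRecord], dict]:
    """Detect gain/loss differentially correlated pairs.

    ``p_diff`` screens the Fisher-combined difference p-value; the
    direction filter acts on the sign of z_B - z_A per dataset.  Both
    networks must share the same node universe (the DEGs).
    """
    if set(network_A.nodes) != set(network_B.nodes):
        raise ValueError("both networks must be built on the same DEG universe")
    genes = sorted(network_A.nodes)
    if k_required is None:
        k_required = len(datasets)
    if len(genes) < 2:
        empty_counts = {"n_pairs": 0, "n_candidates": 0, "n_significant": 0, "n_dcps": 0}
        return ([], empty_counts) if with_counts else []

    R_A, P_A, N_A, idx = condition_pair_stats(datasets, genes, "A")
    R_B, P_B, N_B, _ = condition_pair_stats(datasets, genes, "B")
    iu, ju = idx

    candidate = _condition_support(P_A, R_A, k_required, p_screen) | _condition_support(
        P_B, R_B, k_required, p_screen
    )

    # per-dataset Fisher z difference (B relative to A)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (
            np.isfinite(R_A)
            & np.isfinite(R_B)
            & (np.abs(R_A) < 1.0)
            & (np.abs(R_B) < 1.0)
            & (N_A >= 4)
            & (N_B >= 4)
        )
        zdiff = np.where(
            ok,
            (np.arctanh(np.clip(R_B, -0.999999, 0.999999))
             - np.arctanh(np.clip(R_A, -0.999999, 0.999999)))
            / np.sqrt(1.0 / np.maximum(N_B - 3, 1) + 1.0 / np.maximum(N_A - 3, 1)),
            np.nan,
        )
        p_d = np.where(ok, 2.0 * stats.norm.sf(np.abs(zdiff)), np.nan)
    s_d = np.where(np.isfinite(zdiff), np.sign(zdiff), 0.0)

    p_d = np.where(candidate[None, :], p_d, np.nan)
    res = meta_screen(
        p_d,
        s_d,
        k_required=k_required,
        p_within=p_diff,
        q_threshold=q_diff,
        support_rule="combined",
    )

    records = []
    for k in np.flatnonzero(res.accepted):
        i, j = genes[int(iu[k])], genes[int(ju[k])]
        in_a, in_b = network_A.has_edge(i, j), network_B.has_edge(i, j)
        if in_a == in_b:  # absent from both, or present in both: not a DCP
            continue
        host = "B" if in_b else "A"
        net = network_B if in_b else network_A
        records.append(
            DCPRecord(
                gene_i=i,
                gene_j=j,
                r_A=tuple(float(v) for v in R_A[:, k]),
                r_B=tuple(float(v) for v in R_B[:, k]),
                per_dataset_diff_p=tuple(float(v) for v in p_d[:, k]),
                meta=res.summary(k, p_d, s_d),
                change_direction="gain" if in_b else "loss",
                host_network=host,
                sign_in_host=net.edge_sign(i, j),
                regulation_i=deg_directions.get(i, ""),
                regulation_j=deg_directions.get(j, ""),
            )
        )
    counts = {
        "n_pairs": int(iu.size),
        "n_candidates": int(candidate.sum()),
        "n_significant": int(res.accepted.sum()),
        "n_dcps": len(records),
    }
    logger.info(
        "DCP funnel: %(n_pairs)d pairs, %(n_candidates)d candidates, "
        "%(n_significant)d significant differences, %(n_dcps)d DCPs", counts,
    )
    return (records, counts) if with_counts else records


def dcp_table(records: list[DCPRecord]) -> pd.DataFrame:
    """Export layout mirroring the published DCP tables."""
    rows = [
        {
            "gene_i": r.gene_i,
            "gene_j": r.gene_j,
            "change_direction": r.change_direction,
            "host_network": r.host_network,
            "sign_in_host": r.sign_in_host,
            "regulation_i": r.regulation_i,
            "regulation_j": r.regulation_j,
            "combined_p": r.meta.combined_p,
            "q": r.meta.q,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_i", "gene_j", "change_direction", "host_network", "sign_in_host",
            "regulation_i", "regulation_j", "combined_p", "q",
        ],
    )


def dc_genes(records: list[DCPRecord], change_direction: str | None = None) -> set[str]:
    """Genes participating in at least one DCP (optionally gain- or loss-only)."""
    out: set[str] = set()
    for r in records:
        if change_direction is None or r.change_direction == change_direction:
            out |= {r.gene_i, r.gene_j}
    return out
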