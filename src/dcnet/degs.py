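"""Differential expression across datasets (DEG calling).

Per dataset each gene gets a paired t-test (when the design is paired) or
a Welch two-sample t-test; per-dataset signs then pass the cross-dataset
direction filter, the agreeing p-values are Fisher-combined and BH FDR is
applied over all genes surviving the filter.  DEGs are the node set of
every downstream network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset
from .meta import MetaSummary, meta_screen

__all__ = ["TTestResult", "GeneStat", "paired_t", "unpaired_t", "call_degs", "deg_table"]

logger = logging.getLogger(__name__)


class TTestResult(NamedTuple):
    t: float
    p: float
    sign: int
    testable: bool


@dataclass(frozen=True)
class GeneStat:
    """Cross-dataset differential-expression summary for one gene."""

    gene: str
    meta: MetaSummary
    direction: str  # 'UP', 'DN' or '' when no consensus
    is_deg: bool
    per_dataset_effect: tuple  # mean(B) - mean(A) in log-expression units


def _finalize(t: np.ndarray, p: np.ndarray, mean_diff: np.ndarray, zero_sd: np.ndarray) -> None:
    """Shared degenerate-case handling for vectorised t-tests (in place).

    Zero-variance genes: a non-zero mean difference is overwhelming
    evidence (p -> 0, infinite t); an identically-zero difference is a null
    result (t = 0, p = 1).
    """
    exact = zero_sd & (mean_diff != 0.0)
    null = zero_sd & (mean_diff == 0.0)
    t[exact] = np.inf * np.sign(mean_diff[exact])
    p[exact] = 0.0
    t[null] = 0.0
    p[null] = 1.0


def _paired_stats(ds: ExpressionDataset, genes: list[str]) -> tuple[np.ndarray, ...]:
    """Vectorised classical paired t over per-pair (B - A) differences."""
    xa, xb = ds.paired_matrices(genes=genes)
    d = xb - xa
    finite = np.isfinite(d)
    n = finite.sum(axis=1).astype(float)
    d0 = np.where(finite, d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = d0.sum(axis=1) / n
        var = np.where(
            n > 1, (np.where(finite, (d - mean[:, None]) ** 2, 0.0)).sum(axis=1) / (n - 1), np.nan
        )
        sd = np.sqrt(var)
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 1.0, 1.0))
    _finalize(t, p, mean, (sd == 0.0) & (n >= 2))
    untestable = n < 2
    t[untestable] = np.nan
    p[untestable] = np.nan
    return t, p, np.where(untestable, np.nan, mean)


def _welch_stats(ds: ExpressionDataset, genes: list[str]) -> tuple[np.ndarray, ...]:
    """Vectorised Welch two-sample t (B vs A) with complete-case samples."""
    out_t, out_p, out_eff = [], [], []
    xa = ds.condition_matrix("A", genes=genes)
    xb = ds.condition_matrix("B", genes=genes)

    def _moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        finite = np.isfinite(x)
        n = finite.sum(axis=1).astype(float)
        x0 = np.where(finite, x, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = x0.sum(axis=1) / n
            var = np.where(
                n > 1,
                (np.where(finite, (x - mean[:, None]) ** 2, 0.0)).sum(axis=1) / (n - 1),
                np.nan,
            )
        return n, mean, var

    na, ma, va = _moments(xa)
    nb, mb, vb = _moments(xb)
    diff = mb - ma
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = va / na + vb / nb
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / np.maximum(na - 1.0, 1.0) + (vb / nb) ** 2 / np.maximum(nb - 1.0, 1.0)
        )
        p = 2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df) & (df > 0), df, 1.0))
    _finalize(t, p, diff, (se2 == 0.0) & (na >= 2) & (nb >= 2))
    untestable = (na < 2) | (nb < 2)
    t[untestable] = np.nan
    p[untestable] = np.nan
    return t, p, np.where(untestable, np.nan, diff)


def _dataset_stats(ds: ExpressionDataset, genes: list[str]) -> tuple[np.ndarray, ...]:
    return _paired_stats(ds, genes) if ds.pairing else _welch_stats(ds, genes)


def _single(ds: ExpressionDataset, gene: str, paired: bool) -> TTestResult:
    if gene not in ds.values.index:
        raise KeyError(f"gene {gene!r} not in dataset {ds.dataset_id!r}")
    fn = _paired_stats if paired else _welch_stats
    t, p, eff = fn(ds, [gene])
    if not np.isfinite(p[0]):
        return TTestResult(float("nan"), float("nan"), 0, False)
    sign = 0 if eff[0] == 0 else int(np.sign(eff[0]))
    return TTestResult(float(t[0]), float(p[0]), sign, True)


def paired_t(ds: ExpressionDataset, gene: str) -> TTestResult:
    """Classical paired t-test on a gene's per-pair (B - A) differences.

    Fewer than two complete pairs flags the gene untestable; a zero-variance
    non-zero difference is reported as p = 0 (see module notes).
    """
    if ds.pairing is None:
        raise ValueError("paired_t requires a paired dataset")
    return _single(ds, gene, paired=True)


def unpaired_t(ds: ExpressionDataset, gene: str) -> TTestResult:
    """Welch two-sample t-test of condition B versus condition A."""
    return _single(ds, gene, paired=False)


def call_degs(
    datasets: list[ExpressionDataset],
    *,
    p_deg: float = 0.05,
    q_deg: float = 0.10,
    k_required: int | None = None,
    veto: bool = False,
    genes: list[str] | None = None,
) -> list[GeneStat]:
    """Meta-analysed DEG calling over parallel datasets.

    A gene is a DEG when (i) its effect sign agrees in at least
    ``k_required`` datasets, (ii) the agreeing per-dataset p-values are
    below ``p_deg`` in at least ``k_required`` datasets, and (iii) the BH
    q of the Fisher-combined p (over genes passing the filter) is below
    ``q_deg``.  Genes untestable in too many datasets to reach
    ``k_required`` are excluded and logged.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if k_required is None:
        k_required = len(datasets)
    if genes is None:
        genes = sorted({g for ds in datasets for g in ds.genes})
    m = len(datasets)
    P = np.full((m, len(genes)), np.nan)
    S = np.zeros((m, len(genes)))
    E = np.full((m, len(genes)), np.nan)
    for d, ds in enumerate(datasets):
        t, p, eff = _dataset_stats(ds, genes)
        P[d], E[d] = p, eff
        S[d] = np.where(np.isfinite(eff), np.sign(eff), 0.0)

    testable = np.isfinite(P).sum(axis=0)
    n_untestable = int((testable < k_required).sum())
    if n_untestable:
        logger.info("%d genes untestable in enough datasets for k=%d", n_untestable, k_required)

    res = meta_screen(P, S, k_required=k_required, p_within=p_deg, q_threshold=q_deg, veto=veto)
    out = []
    for j, gene in enumerate(genes):
        consensus = int(res.consensus[j])
        direction = {1: "UP", -1: "DN"}.get(consensus, "")
        out.append(
            GeneStat(
                gene=gene,
                meta=res.summary(j, P, S),
                direction=direction,
                is_deg=bool(res.accepted[j]),
                per_dataset_effect=tuple(float(v) for v in E[:, j]),
            )
        )
    return out


def deg_table(stats_list: list[GeneStat]) -> pd.DataFrame:
    """Flatten GeneStat records into the exported DEG TSV layout."""
    rows = []
    for gs in stats_list:
        row: dict = {"gene": gs.gene, "direction": gs.direction, "is_deg": gs.is_deg}
        for d, p in enumerate(gs.meta.per_dataset_p):
            row[f"p_ds{d + 1}"] = p
        row["combined_p"] = gs.meta.combined_p
        row["q"] = gs.meta.q
        rows.append(row)
    return pd.DataFrame(rows)
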