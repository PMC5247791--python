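"""Meta-analysis primitives shared by every stage of the pipeline.

Each analysis stage (differential expression, co-expression edges,
differential correlation, local partial correlation) follows the same
three-step scheme across ``m`` parallel datasets:

1. a *direction filter* — the per-dataset effect (mean difference,
   correlation, correlation difference or partial correlation) must carry
   the same sign in at least ``k_required`` of the ``m`` datasets;
2. Fisher's combined-probability test over the per-dataset p-values of the
   datasets that agree with the consensus direction;
3. Benjamini–Hochberg false-discovery-rate control over the combined
   p-values of the features that survived the filter.

This module implements those three primitives plus a vectorised engine
(:func:`meta_screen`) used by the stage modules so that thousands of gene
pairs can be screened without Python-level loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaSummary",
    "fisher_combine",
    "bh_fdr",
    "direction_filter",
    "meta_screen",
    "MetaScreenResult",
]

# p-values of exactly zero arise from degenerate (zero-variance) tests; they
# are clipped before taking logs so the combined statistic becomes +inf and
# the combined p-value 0, preserving the "overwhelming evidence" semantics.
_TINY = 1e-300


@dataclass(frozen=True)
class MetaSummary:
    """Per-feature cross-dataset evidence summary.

    Attributes
    ----------
    per_dataset_p : tuple of float
        Two-sided per-dataset p-values (NaN where the feature was
        untestable in that dataset).
    per_dataset_sign : tuple of int
        Sign of the per-dataset effect, in {-1, 0, +1}.
    n_agreeing : int
        Number of datasets whose sign equals the consensus sign.
    consensus_sign : int
        The majority sign (0 if no direction reached consensus).
    combined_p : float
        Fisher combined probability over the agreeing datasets.
    q : float
        BH-adjusted combined p (NaN when the feature never entered the
        FDR-controlled candidate set).
    """

    per_dataset_p: tuple
    per_dataset_sign: tuple
    n_agreeing: int
    consensus_sign: int
    combined_p: float
    q: float = float("nan")


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's combined probability test.

    ``X = -2 * sum(log p_i)`` is referred to the upper tail of a chi-square
    distribution with ``2 m`` degrees of freedom.  With a single p-value the
    transform is the identity.

    Raises
    ------
    ValueError
        If the list is empty or any p lies outside (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Order-preserving with the input; an empty input yields an empty array.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_filter(
    signs: Sequence[int],
    k_required: int,
    pvalues: Sequence[float] | None = None,
    veto: bool = False,
    veto_p: float = 0.05,
) -> tuple[bool, int]:
    """Cross-dataset sign-consistency filter.

    A feature passes when one sign in {-1, +1} occurs in at least
    ``k_required`` datasets.  Zero signs (exact null effects or untestable
    datasets) count toward neither direction.  When two opposite signs tie
    at or above ``k_required`` the filter fails (no consensus).

    With ``veto=True`` a single dataset carrying the opposite sign at
    nominal significance (its own p-value below ``veto_p``) vetoes the
    feature; the default is no veto.

    Returns
    -------
    (passed, consensus_sign)
    """
    s = np.sign(np.asarray(list(signs), dtype=float)).astype(int)
    m = s.size
    if not 1 <= k_required <= m:
        raise ValueError(f"k_required must lie in [1, {m}]")
    npos = int((s > 0).sum())
    nneg = int((s < 0).sum())
    if npos > nneg:
        consensus, n_agree = 1, npos
    elif nneg > npos:
        consensus, n_agree = -1, nneg
    else:
        return False, 0
    if n_agree < k_required:
        return False, 0
    if veto:
        p = np.asarray(list(pvalues), dtype=float) if pvalues is not None else None
        if p is None:
            raise ValueError("veto=True requires per-dataset p-values")
        opposed = (s == -consensus) & np.isfinite(p) & (p < veto_p)
        if opposed.any():
            return False, 0
    return True, consensus


@dataclass
class MetaScreenResult:
    """Vectorised output of :func:`meta_screen` over N features."""

    consensus: np.ndarray       # (N,) int, in {-1, 0, +1}
    n_agreeing: np.ndarray      # (N,) int
    n_support: np.ndarray       # (N,) int, agreeing AND p < p_within
    pass_direction: np.ndarray  # (N,) bool
    combined_p: np.ndarray      # (N,) float
    q: np.ndarray               # (N,) float, NaN outside the candidate set
    candidate: np.ndarray       # (N,) bool, features entered into the FDR
    accepted: np.ndarray        # (N,) bool, candidate AND q < q_threshold

    def summary(self, j: int, p: np.ndarray, sign: np.ndarray) -> MetaSummary:
        """Assemble the per-feature :class:`MetaSummary` for feature ``j``."""
        return MetaSummary(
            per_dataset_p=tuple(float(v) for v in p[:, j]),
            per_dataset_sign=tuple(int(v) for v in sign[:, j]),
            n_agreeing=int(self.n_agreeing[j]),
            consensus_sign=int(self.consensus[j]),
            combined_p=float(self.combined_p[j]),
            q=float(self.q[j]),
        )


def meta_screen(
    p: np.ndarray,
    sign: np.ndarray,
    *,
    k_required: int,
    p_within: float,
    q_threshold: float,
    support_rule: str = "per_dataset",
    veto: bool = False,
) -> MetaScreenResult:
    """Run the direction-filter / Fisher / BH cascade over N features at once.

    Parameters
    ----------
    p, sign : (m, N) arrays
        Per-dataset two-sided p-values and effect signs.  NaN p-values mark
        untestable dataset/feature combinations; their signs are ignored.
    k_required : int
        Datasets that must agree in direction.
    p_within : float
        Stage-level nominal threshold.  Under ``support_rule='per_dataset'``
        a candidate additionally needs ``k_required`` agreeing datasets with
        per-dataset p below this value; under ``'combined'`` the combined
        p-value itself must fall below it.
    q_threshold : float
        BH FDR level applied over the candidate set.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    sign = np.atleast_2d(np.asarray(sign, dtype=float))
    if p.shape != sign.shape:
        raise ValueError("p and sign must have identical shape")
    m, n = p.shape
    if not 1 <= k_required <= m:
        raise ValueError(f"k_required must lie in [1, {m}]")
    if support_rule not in ("per_dataset", "combined"):
        raise ValueError("support_rule must be 'per_dataset' or 'combined'")

    valid = np.isfinite(p)
    s = np.where(valid, np.sign(sign), 0.0).astype(int)
    npos = (s > 0).sum(axis=0)
    nneg = (s < 0).sum(axis=0)
    consensus = np.where(npos > nneg, 1, np.where(nneg > npos, -1, 0))
    n_agreeing = np.where(consensus == 1, npos, np.where(consensus == -1, nneg, 0))
    pass_direction = (consensus != 0) & (n_agreeing >= k_required)
    if veto:
        opposed = (s == -consensus[None, :]) & valid & (p < p_within) & (consensus != 0)[None, :]
        pass_direction &= ~opposed.any(axis=0)

    agree = (s == consensus[None, :]) & (consensus != 0)[None, :] & valid
    support = agree & (p < p_within)
    n_support = support.sum(axis=0)

    x = np.where(agree, -2.0 * np.log(np.clip(p, _TINY, 1.0)), 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        combined = np.where(
            n_agreeing > 0, stats.chi2.sf(x, 2 * np.maximum(n_agreeing, 1)), 1.0
        )

    if support_rule == "per_dataset":
        candidate = pass_direction & (n_support >= k_required)
    else:
        candidate = pass_direction & (combined < p_within)

    q = np.full(n, np.nan)
    if candidate.any():
        q[candidate] = bh_fdr(combined[candidate])
    accepted = candidate & (q < q_threshold)
    return MetaScreenResult(
        consensus=consensus,
        n_agreeing=n_agreeing,
        n_support=n_support,
        pass_direction=pass_direction,
        combined_p=combined,
        q=q,
        candidate=candidate,
        accepted=accepted,
    )
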