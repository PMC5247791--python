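"""Causal-gene enrichment and knockdown growth metrics.

The enrichment half asks whether a gene group (e.g. the DC genes of the
gain DCPs) is over-represented for causal genes relative to the remaining
background genes, via a one-sided Fisher exact test on the 2x2 table.

The knockdown half implements the growth-curve normalisation used for
siRNA experiments: the A/B index (cell index after / before treatment)
and the inhibition index ((control A/B - treatment A/B) / control A/B;
positive = growth inhibition), with a one-sample, one-sided t-test over
replicate inhibition indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "enrichment_of_set",
    "ab_index",
    "inhibition_index",
    "one_sided_t",
    "KnockdownResult",
    "knockdown_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a group-vs-background by causal-vs-not cross table.

    a = causal in group, b = non-causal in group,
    c = causal in background, d = non-causal in background.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(
    table: ContingencyTable2x2, alternative: str = "greater"
) -> float:
    """Fisher's exact test on a 2x2 table (hypergeometric tail).

    ``alternative`` is one of 'greater', 'less' or 'two-sided' (the
    two-sided p sums the probabilities of tables at most as probable as
    the observed one).  A zero margin yields p = 1.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def enrichment_of_set(
    group: Iterable[str], causal: Iterable[str], background: Iterable[str]
) -> tuple[ContingencyTable2x2, float, float]:
    """Over-representation of causal genes in a group versus a background.

    The background contributes only its genes outside the group.  Returns
    (table, odds ratio with Haldane 0.5 correction on zero cells,
    one-sided 'greater' Fisher p).  An empty group returns p = 1.
    """
    group = set(group)
    causal = set(causal)
    rest = set(background) - group
    table = ContingencyTable2x2(
        a=len(group & causal),
        b=len(group - causal),
        c=len(rest & causal),
        d=len(rest - causal),
    )
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    if not group:
        return table, odds_ratio, 1.0
    return table, odds_ratio, fisher_exact_2x2(table, "greater")


def ab_index(cell_index_before: float, cell_index_after: float) -> float:
    """After/before treatment cell-index ratio (growth normalisation)."""
    if cell_index_before <= 0:
        raise ValueError("cell index before treatment must be positive")
    return cell_index_after / cell_index_before


def inhibition_index(control_ab: float, treatment_ab: float) -> float:
    """(control A/B - treatment A/B) / control A/B.

    Positive values mean the knockdown inhibited growth, zero means no
    difference from the non-targeting control, negative means the cells
    grew faster after the knockdown.
    """
    if control_ab <= 0:
        raise ValueError("control A/B index must be positive")
    return (control_ab - treatment_ab) / control_ab


def one_sided_t(values: Sequence[float], alternative: str) -> float:
    """One-sample, one-sided t-test of the mean against zero.

    ``alternative`` is 'mean_gt_0' or 'mean_lt_0'.  Zero-variance input
    returns p = 0 when the common value lies strictly on the alternative
    side and 1 otherwise.
    """
    if alternative not in ("mean_gt_0", "mean_lt_0"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("at least two values are required")
    side = "greater" if alternative == "mean_gt_0" else "less"
    if np.ptp(x) == 0.0:
        mean = x[0]
        on_side = mean > 0 if side == "greater" else mean < 0
        return 0.0 if on_side else 1.0
    return float(stats.ttest_1samp(x, 0.0, alternative=side).pvalue)


@dataclass(frozen=True)
class KnockdownResult:
    """Replicate-level knockdown growth summary for one treatment."""

    treatment: str
    ab_index_control: tuple
    ab_index_treatment: tuple
    inhibition_index: tuple
    direction: str  # 'suppressor_expected' (mean < 0) or 'oncogene_expected' (> 0)
    p: float


def knockdown_test(
    treatment: str,
    control_before: Sequence[float],
    control_after: Sequence[float],
    treatment_before: Sequence[float],
    treatment_after: Sequence[float],
    direction: str,
) -> KnockdownResult:
    """Full two-step normalisation plus one-sided t over replicates.

    Each replicate experiment supplies control and treated cell indices
    before and after treatment; the expected direction encodes the
    biological hypothesis ('oncogene_expected': knockdown inhibits growth,
    inhibition index > 0; 'suppressor_expected': growth increases, < 0).
    """
    if direction not in ("suppressor_expected", "oncogene_expected"):
        raise ValueError(f"unknown direction {direction!r}")
    lengths = {len(control_before), len(control_after), len(treatment_before), len(treatment_after)}
    if len(lengths) != 1:
        raise ValueError("replicate lists must have equal length")
    ab_c = tuple(ab_index(b, a) for b, a in zip(control_before, control_after))
    ab_t = tuple(ab_index(b, a) for b, a in zip(treatment_before, treatment_after))
    inh = tuple(inhibition_index(c, t) for c, t in zip(ab_c, ab_t))
    alt = "mean_gt_0" if direction == "oncogene_expected" else "mean_lt_0"
    return KnockdownResult(
        treatment=treatment,
        ab_index_control=ab_c,
        ab_index_treatment=ab_t,
        inhibition_index=inh,
        direction=direction,
        p=one_sided_t(inh, alt),
    )
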