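"""Synthetic multi-dataset two-condition expression data with known truth.

The generator emulates the study designs the pipeline targets: m parallel
datasets per condition, planted mean-shift DEGs, per-condition correlation
structure with gain and loss pairs, causal hub genes whose correlations
appear only in the perturbed condition, an optional paired design and
optional inter-sample heterogeneity (different tumours activating
different causal hubs).

Structure of the planted truth
------------------------------
* condition A (reference) and condition B (perturbed) each have a target
  correlation matrix with unit diagonal;
* *gain* pairs: zero correlation in A, ``r_planted`` in B.  Positive
  semi-definiteness rules out star hubs with independent leaves, so causal
  hubs are planted as equicorrelated cliques ("blocks"): every
  within-block pair is a gain and the block's first gene is the designated
  causal hub.  ``n_gain`` must therefore equal ``n_causal * C(k, 2)`` for
  an integer block size k;
* *loss* pairs: disjoint gene pairs correlated at ``r_planted`` in A and
  uncorrelated in B;
* *shared* pairs: disjoint pairs correlated identically in both
  conditions — a non-differential co-expression backbone;
* DEG mean shifts (condition B only) of ``effect_size`` marginal standard
  deviations; all genes participating in planted correlation structure are
  DEGs with a common regulation direction per block/pair, so that their
  positive correlations are concordant with the PUC filter.

Sampling is multivariate normal per dataset and condition; the paired
design shares a per-pair, per-gene intercept carved out of the unit
marginal variance so planted correlations stay exact (see docs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from math import isqrt
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = ["TruthConfig", "SyntheticTruth", "generate_truth", "sample_datasets"]

logger = logging.getLogger(__name__)

# Variance of the per-pair shared intercept in paired designs.  Must stay
# below the smallest eigenvalue of the planted correlation matrices so the
# residual covariance C - tau2*I remains positive definite; it is halved
# toward that bound automatically for extreme r_planted.
PAIR_INTERCEPT_VAR = 0.15
BASELINE_MEAN = 7.0   # log-scale baseline expression
BASELINE_SD = 1.0
PSD_TOL = 0.02        # max allowed drift of planted entries after PSD repair


@dataclass(frozen=True)
class TruthConfig:
    """Planted-truth configuration (defaults mirror the two-dataset,
    12 + 12 paired knockout design the pipeline is calibrated on)."""

    n_genes: int = 300
    n_causal: int = 5
    n_deg: int = 80
    n_gain: int = 50
    n_loss: int = 10
    n_shared: int = 10
    r_planted: float = 0.8
    effect_size: float = 1.5

    def validate(self) -> int:
        """Check feasibility; returns the gain-block size k."""
        if not 0.0 < self.r_planted < 1.0:
            raise ValueError("r_planted must lie in (0, 1)")
        if self.n_causal < 0 or self.n_deg < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_causal == 0:
            if self.n_gain:
                raise ValueError("gain pairs require n_causal >= 1")
            k = 0
        else:
            if self.n_gain % self.n_causal:
                raise ValueError("n_gain must be n_causal * C(k, 2) for integer k")
            per_block = self.n_gain // self.n_causal
            # per_block = k*(k-1)/2  ->  k = (1 + sqrt(1 + 8*per_block)) / 2
            disc = 1 + 8 * per_block
            root = isqrt(disc)
            if root * root != disc or (1 + root) % 2:
                raise ValueError("n_gain must be n_causal * C(k, 2) for integer k")
            k = (1 + root) // 2
        n_structured = self.n_causal * k + 2 * self.n_loss + 2 * self.n_shared
        if n_structured > self.n_deg:
            raise ValueError(
                f"planted structure needs {n_structured} DEGs but n_deg={self.n_deg}"
            )
        if self.n_deg > self.n_genes:
            raise ValueError("n_deg cannot exceed n_genes")
        return k


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated study."""

    config: TruthConfig
    seed: int
    genes: list
    deg_truth: dict            # gene -> ('UP'|'DN', effect in SD units)
    corr_A: np.ndarray
    corr_B: np.ndarray
    dcp_truth: dict            # (gene_i, gene_j) -> ('gain'|'loss', r_A, r_B)
    causal_genes: set
    shared_pairs: set = field(default_factory=set)

    @property
    def deg_genes(self) -> set:
        return set(self.deg_truth)

    def gain_pairs(self) -> set:
        return {p for p, (kind, *_ ) in self.dcp_truth.items() if kind == "gain"}

    def loss_pairs(self) -> set:
        return {p for p, (kind, *_ ) in self.dcp_truth.items() if kind == "loss"}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "seed": self.seed,
            "genes": self.genes,
            "deg_truth": {g: list(v) for g, v in self.deg_truth.items()},
            "dcp_truth": {f"{i}|{j}": list(v) for (i, j), v in self.dcp_truth.items()},
            "causal_genes": sorted(self.causal_genes),
            "shared_pairs": sorted(f"{i}|{j}" for i, j in self.shared_pairs),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _nearest_psd(c: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping followed by unit-diagonal renormalisation."""
    w, v = np.linalg.eigh(c)
    if w.min() >= 0.0:
        return c
    logger.info("repairing non-PSD correlation matrix (min eig %.3g)", w.min())
    w = np.clip(w, 1e-8, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_truth(config: TruthConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Build the planted truth: DEG directions, correlation matrices,
    gain/loss/shared pairs and the causal hub set.  Fully reproducible
    from the seed."""
    config = config or TruthConfig()
    block_k = config.validate()
    rng = np.random.default_rng(seed)
    g = config.n_genes
    genes = [f"G{i:04d}" for i in range(g)]

    order = rng.permutation(g)
    deg_idx = sorted(order[: config.n_deg])
    pool = list(deg_idx)

    def take(k: int) -> list[int]:
        out, rest = pool[:k], pool[k:]
        pool[:] = rest
        return out

    corr_A = np.eye(g)
    corr_B = np.eye(g)
    deg_truth: dict[str, tuple] = {}
    dcp_truth: dict[tuple, tuple] = {}
    causal: set[str] = set()
    shared_pairs: set[tuple] = set()
    r = config.r_planted

    def plant_block(members: list[int], mats: list[np.ndarray]) -> None:
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                for m in mats:
                    m[i, j] = m[j, i] = r

    def name_pair(i: int, j: int) -> tuple[str, str]:
        return tuple(sorted((genes[i], genes[j])))  # type: ignore[return-value]

    # causal hub blocks: equicorrelated cliques present only in condition B
    for b in range(config.n_causal):
        members = take(block_k)
        plant_block(members, [corr_B])
        direction = "UP" if b % 2 == 0 else "DN"
        causal.add(genes[members[0]])
        for m in members:
            deg_truth[genes[m]] = (direction, config.effect_size)
        for a in range(len(members)):
            for c in range(a + 1, len(members)):
                dcp_truth[name_pair(members[a], members[c])] = ("gain", 0.0, r)

    # loss pairs: correlated in A only
    for p in range(config.n_loss):
        i, j = take(2)
        plant_block([i, j], [corr_A])
        direction = "UP" if p % 2 == 0 else "DN"
        for m in (i, j):
            deg_truth[genes[m]] = (direction, config.effect_size)
        dcp_truth[name_pair(i, j)] = ("loss", r, 0.0)

    # shared backbone: correlated identically in both conditions
    for p in range(config.n_shared):
        i, j = take(2)
        plant_block([i, j], [corr_A, corr_B])
        direction = "UP" if p % 2 == 0 else "DN"
        for m in (i, j):
            deg_truth[genes[m]] = (direction, config.effect_size)
        shared_pairs.add(name_pair(i, j))

    # remaining DEGs: mean shift only, no planted correlation
    for t, m in enumerate(pool):
        deg_truth[genes[m]] = ("UP" if t % 2 == 0 else "DN", config.effect_size)

    corr_A = _nearest_psd(corr_A)
    corr_B = _nearest_psd(corr_B)
    gene_pos = {gname: i for i, gname in enumerate(genes)}
    for (gi, gj), (kind, ra, rb) in dcp_truth.items():
        i, j = gene_pos[gi], gene_pos[gj]
        if abs(corr_A[i, j] - ra) > PSD_TOL or abs(corr_B[i, j] - rb) > PSD_TOL:
            raise ValueError("PSD repair moved a planted correlation beyond tolerance")

    return SyntheticTruth(
        config=config,
        seed=seed,
        genes=genes,
        deg_truth=deg_truth,
        corr_A=corr_A,
        corr_B=corr_B,
        dcp_truth=dcp_truth,
        causal_genes=causal,
        shared_pairs=shared_pairs,
    )


def _hub_blocks(truth: SyntheticTruth) -> list[list[int]]:
    """Recover causal-block member indices from the truth object."""
    pos = {g: i for i, g in enumerate(truth.genes)}
    blocks: dict[str, set[int]] = {}
    for (gi, gj), (kind, *_rest) in truth.dcp_truth.items():
        if kind != "gain":
            continue
        for hub in truth.causal_genes:
            if hub in (gi, gj):
                blocks.setdefault(hub, {pos[hub]}).update({pos[gi], pos[gj]})
    return [sorted(v) for _, v in sorted(blocks.items())]


def sample_datasets(
    truth: SyntheticTruth,
    m_datasets: int = 2,
    n_per_condition: int = 12,
    paired: bool = True,
    heterogeneity: float = 0.0,
    seed: int = 0,
) -> list[ExpressionDataset]:
    """Draw ``m_datasets`` two-condition expression datasets from the truth.

    Condition A samples follow MVN(baseline, corr_A); condition B samples
    follow MVN(baseline + effect, corr_B).  With ``paired=True`` each A/B
    sample pair shares a per-gene random intercept (variance
    ``PAIR_INTERCEPT_VAR``) carved out of the unit marginal variance, so
    within-sample correlations still equal the planted matrices while
    paired differences have variance 2*(1 - tau2) < 2.  ``heterogeneity``
    h in [0, 1] makes each condition-B sample activate each causal-hub
    block independently with probability 1 - h (an inactive block reverts
    to the reference structure for that sample), emulating multi-causal
    tumours.  All randomness flows from ``seed``.
    """
    if n_per_condition < 4:
        raise ValueError("n_per_condition must be >= 4")
    if not 0.0 <= heterogeneity <= 1.0:
        raise ValueError("heterogeneity must lie in [0, 1]")
    g = len(truth.genes)
    cfg = truth.config
    mu = np.zeros(g)
    directions = np.zeros(g)
    for i, gene in enumerate(truth.genes):
        if gene in truth.deg_truth:
            d, eff = truth.deg_truth[gene]
            mu[i] = eff if d == "UP" else -eff
            directions[i] = 1 if d == "UP" else -1

    tau2 = 0.0
    if paired:
        lam_min = min(
            float(np.linalg.eigvalsh(truth.corr_A)[0]),
            float(np.linalg.eigvalsh(truth.corr_B)[0]),
        )
        tau2 = min(PAIR_INTERCEPT_VAR, 0.5 * lam_min)

    blocks = _hub_blocks(truth)
    children = np.random.SeedSequence(seed).spawn(m_datasets)
    datasets = []
    for d in range(m_datasets):
        rng = np.random.default_rng(children[d])
        baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=g)

        chol_A = np.linalg.cholesky(truth.corr_A - tau2 * np.eye(g))
        chol_cache: dict[tuple, np.ndarray] = {}

        def chol_b(pattern: tuple) -> np.ndarray:
            if pattern not in chol_cache:
                c = truth.corr_B.copy()
                for active, members in zip(pattern, blocks):
                    if not active:
                        idx = np.ix_(members, members)
                        c[idx] = truth.corr_A[idx]
                chol_cache[pattern] = np.linalg.cholesky(c - tau2 * np.eye(g))
            return chol_cache[pattern]

        n = n_per_condition
        xa = (chol_A @ rng.standard_normal((g, n)))
        xb = np.empty((g, n))
        for s in range(n):
            if blocks and heterogeneity > 0.0:
                pattern = tuple(rng.random(len(blocks)) >= heterogeneity)
            else:
                pattern = tuple(True for _ in blocks)
            xb[:, s] = chol_b(pattern) @ rng.standard_normal(g)
        if paired and tau2 > 0.0:
            shared = np.sqrt(tau2) * rng.standard_normal((g, n))
            xa += shared
            xb += shared
        xa += baseline[:, None]
        xb += (baseline + mu)[:, None]

        a_names = [f"D{d + 1}A{s + 1:02d}" for s in range(n)]
        b_names = [f"D{d + 1}B{s + 1:02d}" for s in range(n)]
        values = pd.DataFrame(
            np.hstack([xa, xb]), index=truth.genes, columns=a_names + b_names
        )
        condition = pd.Series(["A"] * n + ["B"] * n, index=a_names + b_names)
        pairing = dict(zip(a_names, b_names)) if paired else None
        datasets.append(
            ExpressionDataset(
                dataset_id=f"sim{d + 1}",
                values=values,
                condition=condition,
                pairing=pairing,
            )
        )
    return datasets
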