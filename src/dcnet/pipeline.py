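"""End-to-end orchestration: DEGs -> networks -> DCPs -> topology -> enrichment.

Two named presets encode the two study designs the pipeline was built
around: ``bcko`` (two paired mouse datasets, Pearson networks) and
``cervical`` (five unpaired tumour datasets, local partial correlation
networks).  All thresholds are configurable; the presets carry the
published defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .degs import GeneStat, call_degs, deg_table
from .diffcorr import DCPRecord, call_dcps, dc_genes, dcp_table
from .enrichment import enrichment_of_set
from .io import ExpressionDataset, write_cytoscape_tables
from .lpc import build_lpc_network
from .networks import CoexpressionNetwork, build_network
from .simulate import SyntheticTruth, TruthConfig, generate_truth, sample_datasets
from .topology import compare_dc_topology, topology_table

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "PRESETS",
    "run_pipeline",
    "recovery_report",
]

logger = logging.getLogger(__name__)

PRESETS: dict[str, dict] = {
    # two paired datasets; direction filter 2-of-2
    "bcko": dict(
        mode="pearson", k_required=2,
        p_deg=0.05, q_deg=0.10,
        p_corr=0.20, q_corr=0.025,
        p_screen=0.20, p_diff=0.10, q_diff=0.02,
        p_lpc_screen=0.40, q_lpc=0.05,
    ),
    # five unpaired datasets; direction filter 3-of-5; LPC networks
    "cervical": dict(
        mode="lpc", k_required=3,
        p_deg=0.05, q_deg=0.10,
        p_corr=0.10, q_corr=1e-8,
        p_screen=0.10, p_diff=0.10, q_diff=0.0025,
        p_lpc_screen=0.40, q_lpc=0.05,
    ),
}


@dataclass
class PipelineConfig:
    """All thresholds and switches of a pipeline run."""

    mode: str = "pearson"          # 'pearson' or 'lpc' network inference
    k_required: int = 2            # datasets that must agree in direction
    p_deg: float = 0.05
    q_deg: float = 0.10
    p_corr: float = 0.20
    q_corr: float = 0.025
    p_screen: float = 0.20
    p_diff: float = 0.10
    q_diff: float = 0.02
    p_lpc_screen: float = 0.40
    q_lpc: float = 0.05
    seed: int = 0
    key_drivers: list = field(default_factory=list)
    deg_list: dict = field(default_factory=dict)  # optional precomputed gene -> UP/DN

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        params = {**PRESETS[name], **overrides}
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        preset = raw.pop("preset", None)
        return cls.preset(preset, **raw) if preset else cls(**raw)

    def validate(self, n_datasets: int) -> None:
        for name in ("p_deg", "q_deg", "p_corr", "q_corr", "p_screen",
                     "p_diff", "q_diff", "p_lpc_screen", "q_lpc"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.mode not in ("pearson", "lpc"):
            raise ValueError("mode must be 'pearson' or 'lpc'")
        if not 1 <= self.k_required <= n_datasets:
            raise ValueError("k_required must not exceed the number of datasets")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline output."""

    config: PipelineConfig
    gene_stats: list
    deg_directions: dict
    network_A: CoexpressionNetwork
    network_B: CoexpressionNetwork
    dcps: list
    topology: pd.DataFrame | None = None
    topology_stats: dict | None = None
    enrichment: dict | None = None
    counts: dict = field(default_factory=dict)

    @property
    def deg_frame(self) -> pd.DataFrame:
        return deg_table(self.gene_stats)

    @property
    def dcp_frame(self) -> pd.DataFrame:
        return dcp_table(self.dcps)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(
    config: PipelineConfig,
    datasets: list[ExpressionDataset],
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute DEG calling, network inference, DCP detection and (when key
    drivers are configured) topology and enrichment, in order.

    Outputs are written atomically under ``outdir`` when given, together
    with a manifest recording the config hash, seed and package version.
    """
    config.validate(len(datasets))

    gene_stats: list[GeneStat] = []
    if config.deg_list:
        deg_directions = dict(config.deg_list)
    else:
        gene_stats = _stage("degs")(call_degs)(
            datasets, p_deg=config.p_deg, q_deg=config.q_deg, k_required=config.k_required
        )
        deg_directions = {gs.gene: gs.direction for gs in gene_stats if gs.is_deg}

    builder = _stage("networks")(
        build_network if config.mode == "pearson" else build_lpc_network
    )
    if config.mode == "pearson":
        kwargs = dict(p_corr=config.p_corr, q_corr=config.q_corr, k_required=config.k_required)
    else:
        kwargs = dict(
            p_lpc_screen=config.p_lpc_screen, q_lpc=config.q_lpc, k_required=config.k_required
        )
    network_A = builder(datasets, deg_directions, "A", **kwargs)
    network_B = builder(datasets, deg_directions, "B", **kwargs)

    dcps = _stage("dcps")(call_dcps)(
        datasets, network_A, network_B, deg_directions,
        p_screen=config.p_screen, p_diff=config.p_diff,
        q_diff=config.q_diff, k_required=config.k_required,
    )

    result = PipelineResult(
        config=config,
        gene_stats=gene_stats,
        deg_directions=deg_directions,
        network_A=network_A,
        network_B=network_B,
        dcps=dcps,
        counts={
            "n_degs": len(deg_directions),
            "n_edges_A": network_A.n_edges,
            "n_edges_B": network_B.n_edges,
            "n_dcps": len(dcps),
            "n_gains": sum(r.change_direction == "gain" for r in dcps),
            "n_losses": sum(r.change_direction == "loss" for r in dcps),
        },
    )

    dc = dc_genes(dcps)
    if config.key_drivers:
        drivers = set(config.key_drivers)
        result.topology = _stage("topology")(topology_table)(network_B, drivers, dc)
        result.topology_stats = _stage("topology")(compare_dc_topology)(
            result.topology, seed=config.seed
        )
        gain_dc = dc_genes(dcps, "gain")
        table, oratio, p = _stage("enrichment")(enrichment_of_set)(
            gain_dc, drivers, set(deg_directions)
        )
        result.enrichment = {
            "gain_dc_table": [table.a, table.b, table.c, table.d],
            "gain_dc_odds_ratio": oratio,
            "gain_dc_p": p,
        }

    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    tmp.replace(path)


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.gene_stats:
        _atomic_write(outdir / "degs.tsv",
                      lambda p: result.deg_frame.to_csv(p, sep="\t", index=False))
    _atomic_write(outdir / "dcps.tsv",
                  lambda p: result.dcp_frame.to_csv(p, sep="\t", index=False))
    dc = dc_genes(result.dcps)
    drivers = set(result.config.key_drivers)
    for net, tag in ((result.network_A, "A"), (result.network_B, "B")):
        ann = {
            g: {"is_deg": True, "is_dc": g in dc, "is_causal": g in drivers}
            for g in net.graph.nodes
        }
        write_cytoscape_tables(
            net, ann, outdir / f"network_{tag}_edges.tsv", outdir / f"network_{tag}_nodes.tsv"
        )
    if result.topology is not None:
        _atomic_write(outdir / "topology.tsv",
                      lambda p: result.topology.to_csv(p, sep="\t", index=False))
    report = {
        "counts": result.counts,
        "topology_stats": result.topology_stats,
        "enrichment": result.enrichment,
    }
    _atomic_write(outdir / "report.json",
                  lambda p: p.write_text(json.dumps(report, indent=1, default=float)))
    cfg = result.config.to_dict()
    manifest = {
        "version": __version__,
        "seed": result.config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    _atomic_write(outdir / "manifest.json",
                  lambda p: p.write_text(json.dumps(manifest, indent=1)))


def recovery_report(result: PipelineResult, truth: SyntheticTruth) -> dict:
    """Confusion-matrix metrics of a run against its planted truth.

    FDR is defined as 0 when there are no discoveries.  Detected-pair
    classification is compared on pairs that are planted DCPs.
    """
    truth_genes = set(truth.genes)
    found_genes = set(result.deg_directions)
    if not found_genes <= truth_genes:
        raise ValueError("result gene universe is not contained in the truth universe")

    def _rates(found: set, planted: set) -> tuple[float, float]:
        tp = len(found & planted)
        sens = tp / len(planted) if planted else float("nan")
        fdr = (len(found) - tp) / len(found) if found else 0.0
        return sens, fdr

    deg_sens, deg_fdr = _rates(found_genes, truth.deg_genes)

    found_pairs = {
        tuple(sorted((r.gene_i, r.gene_j))): r.change_direction for r in result.dcps
    }
    gains, losses = truth.gain_pairs(), truth.loss_pairs()
    found_gain = {p for p, d in found_pairs.items() if d == "gain"}
    found_loss = {p for p, d in found_pairs.items() if d == "loss"}
    dcp_sens, dcp_fdr = _rates(set(found_pairs), gains | losses)
    gain_sens, _ = _rates(found_gain, gains)

    confusion = {
        "gain_as_gain": len(found_gain & gains),
        "gain_as_loss": len(found_loss & gains),
        "loss_as_loss": len(found_loss & losses),
        "loss_as_gain": len(found_gain & losses),
    }
    return {
        "deg_sensitivity": deg_sens,
        "deg_fdr": deg_fdr,
        "dcp_sensitivity": dcp_sens,
        "dcp_fdr": dcp_fdr,
        "gain_sensitivity": gain_sens,
        "gain_loss_confusion": confusion,
    }


def simulate_and_run(
    config: PipelineConfig,
    truth_config: TruthConfig | None = None,
    m_datasets: int = 2,
    n_per_condition: int = 12,
    paired: bool = True,
    heterogeneity: float = 0.0,
    outdir: str | Path | None = None,
) -> tuple[PipelineResult, SyntheticTruth, dict]:
    """Convenience wrapper: simulate a study, run the pipeline, report recovery."""
    truth = generate_truth(truth_config, seed=config.seed)
    datasets = sample_datasets(
        truth, m_datasets=m_datasets, n_per_condition=n_per_condition,
        paired=paired, heterogeneity=heterogeneity, seed=config.seed + 1,
    )
    if not config.key_drivers:
        config = dataclasses.replace(config, key_drivers=sorted(truth.causal_genes))
    result = run_pipeline(config, datasets, outdir=outdir)
    return result, truth, recovery_report(result, truth)
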