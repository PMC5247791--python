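"""Reading, writing and generic preprocessing of expression matrices.

Expression tables are tab-delimited text: one header row of sample
identifiers, first column of gene identifiers, log-scale values.  The
two-condition design (and optional sample pairing) lives in a side
annotation table with columns ``sample``, ``condition`` and optionally
``pair_id``.  Networks are exported as Cytoscape-importable edge and node
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression_table",
    "read_annotation_table",
    "median_normalize",
    "filter_gene_presence",
    "write_cytoscape_tables",
    "read_cytoscape_tables",
]

CONDITIONS = ("A", "B")


@dataclass
class ExpressionDataset:
    """One dataset's gene-by-sample log-expression matrix with design.

    Attributes
    ----------
    dataset_id : str
        Free-text identifier of the dataset.
    values : pandas.DataFrame
        Genes in rows (unique index), samples in columns (unique), floats;
        NaN marks missing measurements.
    condition : pandas.Series
        sample -> 'A' or 'B' ('A' = reference/control, 'B' = perturbed).
    pairing : dict or None
        Optional one-to-one map from A-sample to B-sample (paired design).
    """

    dataset_id: str
    values: pd.DataFrame
    condition: pd.Series
    pairing: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"samples without condition annotation: {missing}")
        self.condition = self.condition.reindex(self.values.columns)
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"conditions must be 'A' or 'B', got {sorted(bad)}")
        self.values = self.values.astype(float)
        if self.pairing is not None:
            a_side, b_side = list(self.pairing), list(self.pairing.values())
            if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
                raise ValueError("pairing must be one-to-one")
            for a, b in self.pairing.items():
                if self.condition.get(a) != "A" or self.condition.get(b) != "B":
                    raise ValueError(f"pair ({a!r}, {b!r}) must map an A-sample to a B-sample")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]

    def condition_matrix(self, condition: str, genes: Iterable[str] | None = None) -> np.ndarray:
        """Gene-by-sample array restricted to one condition.

        Genes absent from this dataset come back as all-NaN rows, so callers
        can align datasets on a common gene universe.
        """
        cols = self.condition_samples(condition)
        frame = self.values[cols]
        if genes is not None:
            frame = frame.reindex(list(genes))
        return frame.to_numpy(dtype=float)

    def paired_matrices(self, genes: Iterable[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Aligned (A, B) gene-by-pair arrays for the paired samples."""
        if self.pairing is None:
            raise ValueError(f"dataset {self.dataset_id!r} has no pairing")
        a_cols = list(self.pairing)
        b_cols = [self.pairing[a] for a in a_cols]
        fa, fb = self.values[a_cols], self.values[b_cols]
        if genes is not None:
            fa, fb = fa.reindex(list(genes)), fb.reindex(list(genes))
        return fa.to_numpy(dtype=float), fb.to_numpy(dtype=float)


def read_annotation_table(path: str | Path) -> tuple[pd.Series, dict[str, str] | None]:
    """Read a sample annotation TSV (columns: sample, condition[, pair_id])."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation file must have columns {sorted(required)}")
    condition = pd.Series(ann["condition"].values, index=ann["sample"].values)
    pairing: dict[str, str] | None = None
    if "pair_id" in ann.columns and ann["pair_id"].notna().any():
        pairing = {}
        for pid, grp in ann.dropna(subset=["pair_id"]).groupby("pair_id"):
            a = grp.loc[grp["condition"] == "A", "sample"].tolist()
            b = grp.loc[grp["condition"] == "B", "sample"].tolist()
            if len(a) != 1 or len(b) != 1:
                raise ValueError(f"pair_id {pid!r} must have exactly one A and one B sample")
            pairing[a[0]] = b[0]
    return condition, pairing


def read_expression_table(
    path: str | Path,
    annotation_path: str | Path | None = None,
    *,
    condition: pd.Series | Mapping[str, str] | None = None,
    pairing: Mapping[str, str] | None = None,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Parse a tab-delimited expression matrix into an :class:`ExpressionDataset`.

    Unparseable cells become missing (NaN); duplicate gene identifiers are a
    hard error; every sample must resolve a condition, either from the side
    annotation file or from the ``condition`` argument.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    if annotation_path is not None:
        condition, pairing = read_annotation_table(annotation_path)
    if condition is None:
        raise ValueError("a condition annotation (side file or argument) is required")
    cond = pd.Series(dict(condition)) if not isinstance(condition, pd.Series) else condition
    return ExpressionDataset(
        dataset_id=dataset_id or Path(path).stem,
        values=values,
        condition=cond,
        pairing=dict(pairing) if pairing else None,
    )


def median_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Subtract each sample's median (over observed genes) from its column.

    Standard array median normalization for log-scale values; idempotent.
    A sample with no observed values at all is an error.
    """
    med = ds.values.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"samples with all values missing: {bad}")
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        values=ds.values - med,
        condition=ds.condition.copy(),
        pairing=dict(ds.pairing) if ds.pairing else None,
    )


def filter_gene_presence(
    datasets: list[ExpressionDataset], min_fraction: float = 0.70
) -> list[str]:
    """Genes observed in at least ``min_fraction`` of all arrays.

    The denominator is the total number of samples pooled over all datasets;
    a gene absent from a dataset counts as missing on that dataset's arrays.
    Returns a sorted gene list.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    universe = sorted({g for ds in datasets for g in ds.genes})
    total = sum(len(ds.samples) for ds in datasets)
    observed = pd.Series(0, index=universe, dtype=float)
    for ds in datasets:
        observed = observed.add(ds.values.notna().sum(axis=1).reindex(universe, fill_value=0))
    keep = observed / total >= min_fraction
    return [g for g in universe if keep[g]]


_NODE_COLUMNS = ["gene", "is_deg", "is_dc", "is_causal", "degree"]
_EDGE_COLUMNS = ["source", "target", "sign", "combined_p", "q"]


def write_cytoscape_tables(
    network,
    annotations: Mapping[str, Mapping[str, bool]],
    edge_path: str | Path,
    node_path: str | Path,
) -> None:
    """Write Cytoscape-style edge and node TSV tables for a network.

    ``annotations`` maps every node to a dict with boolean keys ``is_deg``,
    ``is_dc`` and ``is_causal``; a node without an annotation is an error.
    """
    graph = network.graph
    rows = []
    for u, v, data in sorted(graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
        a, b = sorted((u, v))
        rows.append(
            {
                "source": a,
                "target": b,
                "sign": int(data.get("sign", 0)),
                "combined_p": data.get("combined_p", float("nan")),
                "q": data.get("q", float("nan")),
            }
        )
    edges = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    node_rows = []
    for gene in sorted(graph.nodes):
        if gene not in annotations:
            raise ValueError(f"missing annotation for node {gene!r}")
        ann = annotations[gene]
        node_rows.append(
            {
                "gene": gene,
                "is_deg": bool(ann.get("is_deg", False)),
                "is_dc": bool(ann.get("is_dc", False)),
                "is_causal": bool(ann.get("is_causal", False)),
                "degree": graph.degree(gene),
            }
        )
    nodes = pd.DataFrame(node_rows, columns=_NODE_COLUMNS)
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes.to_csv(node_path, sep="\t", index=False)


def read_cytoscape_tables(edge_path: str | Path, node_path: str | Path, condition: str = "A"):
    """Read edge/node tables written by :func:`write_cytoscape_tables`."""
    from .networks import CoexpressionNetwork
    import networkx as nx

    edges = pd.read_csv(edge_path, sep="\t")
    nodes = pd.read_csv(node_path, sep="\t")
    graph = nx.Graph()
    for _, row in nodes.iterrows():
        graph.add_node(
            str(row["gene"]),
            is_deg=bool(row["is_deg"]),
            is_dc=bool(row["is_dc"]),
            is_causal=bool(row["is_causal"]),
        )
    for _, row in edges.iterrows():
        graph.add_edge(
            str(row["source"]),
            str(row["target"]),
            sign=int(row["sign"]),
            combined_p=float(row["combined_p"]),
            q=float(row["q"]),
        )
    return CoexpressionNetwork(condition=condition, graph=graph)
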