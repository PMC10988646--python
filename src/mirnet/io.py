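"""Readers and writers for every table and graph format the pipeline touches.

Formats are plain text: a tab-separated counts matrix (miRNAs as rows,
subjects as columns, StringTie-style), a CSV/TSV phenotype table, a CSV
edge matrix, GEXF 1.2 / GraphML network documents, and a TSV interaction
table.  All writers are deterministic: fixed row ordering and numbers at
6 significant digits, so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from .datamodel import (
    CohortTable,
    DomainMap,
    ExpressionMatrix,
    InteractionTable,
    ValidationError,
    _COHORT_REQUIRED,
    _INTERACTION_COLUMNS,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_phenotypes",
    "write_phenotypes",
    "write_edge_matrix",
    "read_edge_matrix",
    "write_graph",
    "read_interactions",
    "write_interactions",
    "write_records",
    "read_records",
    "fmt",
]


def fmt(x) -> str:
    """Canonical 6-significant-digit text form of a number."""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def read_counts(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated counts file (first column miRNA ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "mirna"
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna().to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric cell at miRNA {row!r}, subject {col!r}"
            )
        df[col] = numeric.astype(float)
    return ExpressionMatrix(df, normalized=False)


def write_counts(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.counts.copy()
    out.index.name = "mirna"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_phenotypes(path: str | Path, domain_map: DomainMap) -> CohortTable:
    """Read a phenotype CSV/TSV (delimiter sniffed from the header line)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    return CohortTable(df, tests=list(domain_map.tests))


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    cols = _COHORT_REQUIRED + cohort.tests
    cohort.df[cols].to_csv(path, index=False, float_format="%.6g")


EDGE_MATRIX_COLUMNS = ["mirna", "hub", "sign", "rho", "p", "weight"]


def write_edge_matrix(net, path: str | Path) -> None:
    """One CSV row per edge, sorted by (hub, mirna) for stable diffs."""
    rows = []
    for mirna, hub, data in net.graph.edges(data=True):
        # networkx may report either endpoint first
        if net.graph.nodes[mirna]["kind"] != "mirna":
            mirna, hub = hub, mirna
        rows.append(
            {
                "mirna": mirna,
                "hub": hub,
                "sign": net.graph.nodes[hub]["sign"],
                "rho": data["rho"],
                "p": data["p"],
                "weight": data["weight"],
            }
        )
    rows.sort(key=lambda r: (r["hub"], r["mirna"]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EDGE_MATRIX_COLUMNS)
        for r in rows:
            w.writerow(
                [r["mirna"], r["hub"], r["sign"], fmt(r["rho"]), fmt(r["p"]), fmt(r["weight"])]
            )


def read_edge_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EDGE_MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"edge matrix missing columns: {missing}")
    return df


def write_graph(net, path: str | Path, format: str = "gexf") -> None:
    """Export the network as GEXF 1.2 or GraphML.

    Node attributes ``kind``, ``sign`` (hubs only) and ``degree`` and the
    edge attribute ``weight`` are embedded; layout coordinates, when
    present, go into GEXF viz positions or plain x/y GraphML attributes.
    """
    g = nx.Graph()
    for node, data in sorted(net.graph.nodes(data=True)):
        attrs = {"kind": data["kind"], "degree": net.graph.degree(node)}
        if data.get("sign") is not None:
            attrs["sign"] = data["sign"]
        if net.coordinates is not None and node in net.coordinates:
            x, y = net.coordinates[node]
            if format == "gexf":
                attrs["viz"] = {"position": {"x": float(x), "y": float(y), "z": 0.0}}
            else:
                attrs["x"], attrs["y"] = float(x), float(y)
        g.add_node(node, **attrs)
    for u, v, data in sorted(net.graph.edges(data=True)):
        g.add_edge(u, v, weight=float(data["weight"]), rho=float(data["rho"]), p=float(data["p"]))
    if format == "gexf":
        nx.write_gexf(g, path, version="1.2draft")
        # networkx stamps the current date into <meta>; pin it so the
        # document is byte-identical across runs
        import re

        text = Path(path).read_text()
        Path(path).write_text(
            re.sub(r'lastmodifieddate="[0-9-]*"', 'lastmodifieddate="1970-01-01"', text)
        )
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported graph format: {format!r}")


def read_interactions(path: str | Path, panel: pd.DataFrame | None = None) -> InteractionTable:
    """Read a tab-separated miRNA-mRNA interaction prediction table."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_INTERACTION_COLUMNS)
    return InteractionTable(df, panel=panel)


def write_interactions(t: InteractionTable, path: str | Path) -> None:
    t.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Association records as CSV, sorted by (phenotype, mirna)."""
    out = records.sort_values(["phenotype", "mirna"], kind="mergesort")
    out.to_csv(path, index=False, float_format="%.6g")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
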