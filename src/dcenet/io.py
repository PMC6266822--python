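"""Readers and writers for the tabular formats the pipeline touches.

Native dialect is TSV (UTF-8, no quoting). Gene identifiers are opaque
strings; no identifier mapping happens here. Networks interchange as edge-list
TSV (lossless round-trip), SIF and GraphML (Cytoscape-compatible).
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import EDGE_COLUMNS, CoexpressionNetwork, ExpressionMatrix, GeneSetCollection


def read_expression(matrix_path, samplesheet_path) -> ExpressionMatrix:
    """Load a genes-x-samples TSV plus its sample sheet.

    The matrix file carries gene ids in the first column and sample ids in
    the header; the sheet needs columns sample_id, individual_id, group,
    timepoint, sex. Validation (unique ids, full annotation coverage,
    integer time points) happens in :class:`ExpressionMatrix`.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    non_numeric = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
    if non_numeric:
        raise ValueError(f"non-numeric expression values in column(s) {non_numeric[:5]}")

    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    missing = [c for c in ("sample_id", "individual_id", "group", "timepoint", "sex") if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet misses column(s): {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    sheet = sheet.set_index("sample_id")
    return ExpressionMatrix(values.astype(float), sheet)


def write_expression(expr: ExpressionMatrix, matrix_path, samplesheet_path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    # default float formatting = shortest round-trip repr; keep it exact
    df.to_csv(matrix_path, sep="\t")
    sheet = expr.samples.copy()
    sheet.index.name = "sample_id"
    sheet.to_csv(samplesheet_path, sep="\t")


def read_chromosome_map(path) -> dict[str, str]:
    """gene -> chromosome label TSV (columns gene_id, chromosome)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "chromosome" not in df.columns:
        raise ValueError("chromosome map needs columns gene_id, chromosome")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in chromosome map")
    return dict(zip(df["gene_id"], df["chromosome"]))


def write_chromosome_map(chrom: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("gene_id\tchromosome\n")
        for g, c in chrom.items():
            fh.write(f"{g}\t{c}\n")


NETWORK_FORMATS = ("edge_tsv", "sif", "graphml")


def write_network(net: CoexpressionNetwork, path, format: str = "edge_tsv") -> None:
    """Write a network as edge-list TSV, SIF or GraphML.

    edge_tsv keeps full float precision and round-trips exactly through
    :func:`read_network`. SIF encodes the sign as relation "pos"/"neg".
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    if format == "edge_tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(EDGE_COLUMNS) + "\n")
            for row in net.edges.itertuples(index=False):
                fh.write(f"{row.source}\t{row.target}\t{row.weight!r}\t{row.support!r}\t{row.sign}\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for row in net.edges.itertuples(index=False):
                rel = "pos" if row.sign == "+" else "neg"
                fh.write(f"{row.source}\t{rel}\t{row.target}\n")
            for node in sorted(set(net.nodes) - set(net.edges["source"]) - set(net.edges["target"])):
                fh.write(f"{node}\n")
    else:
        g = to_networkx(net)
        nx.write_graphml(g, path)


def read_network(path, format: str = "edge_tsv", provenance: str | None = None) -> CoexpressionNetwork:
    if format not in ("edge_tsv", "graphml"):
        raise ValueError(f"cannot read network format {format!r}")
    path = Path(path)
    if format == "edge_tsv":
        rows = []
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header != list(EDGE_COLUMNS):
                raise ValueError(f"unexpected edge-list header {header}")
            for rec in reader:
                if not rec:
                    continue
                rows.append(
                    {"source": rec[0], "target": rec[1], "weight": float(rec[2]),
                     "support": float(rec[3]), "sign": rec[4]}
                )
        edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
        return CoexpressionNetwork(edges, provenance=provenance or str(path))
    g = nx.read_graphml(path)
    return from_networkx(g, provenance=provenance or g.graph.get("provenance", str(path)))


def to_networkx(net: CoexpressionNetwork) -> nx.Graph:
    g = nx.Graph(provenance=net.provenance)
    g.add_nodes_from(net.nodes)
    for row in net.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight),
                   support=float(row.support), sign=row.sign)
    return g


def from_networkx(g: nx.Graph, provenance: str = "") -> CoexpressionNetwork:
    rows = []
    for a, b, data in g.edges(data=True):
        a, b = (a, b) if a < b else (b, a)
        rows.append({"source": a, "target": b, "weight": float(data["weight"]),
                     "support": float(data["support"]), "sign": data["sign"]})
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    isolated = tuple(n for n in g.nodes if g.degree(n) == 0)
    return CoexpressionNetwork(edges, provenance=provenance, extra_nodes=isolated)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set name TAB description TAB gene TAB gene ...

    Duplicate genes within a line are collapsed; duplicate set names and
    lines with fewer than three fields are errors.
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            coll.add(name, desc, genes)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for name, entry in coll:
            genes = "\t".join(sorted(entry["genes"]))
            fh.write(f"{name}\t{entry['description']}\t{genes}\n")


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for g in genes:
            fh.write(f"{g}\n")
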