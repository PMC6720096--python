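"""Readers and writers for protein networks, regulation tables and stage reports.

All external representations are plain text: tab-separated edge lists
(``proteinA<TAB>proteinB[<TAB>source[<TAB>evidence]]``), GraphML, tab-separated
regulation tables (``mirna<TAB>target[<TAB>source]``) and JSON key-value
reports.  IDs are taken verbatim apart from surrounding-whitespace stripping
(UniProt accessions are case-sensitive by convention); no mapping service is
consulted.  Edge identity is the sorted ID pair, so duplicate rows in either
order merge and the resulting graph is simple and undirected.

A single-column row in a TSV edge list declares an isolated node; this keeps
read/write a strict round trip for networks that contain degree-0 proteins
(disease seed networks routinely do).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np

from .mirna import RegulationTable

logger = logging.getLogger(__name__)

#: tokens that mark the first line of a TSV file as a header
_HEADER_TOKENS = {
    "protein_a", "protein_b", "proteina", "proteinb", "protein1", "protein2",
    "interactor_a", "interactor_b", "node1", "node2", "from", "to",
    "source", "evidence", "database", "mirna", "mir", "target", "gene",
}

_MAX_COLUMNS = 4


def _rows(path: str | Path):
    """Yield (line_number, cells) for content rows, skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        first_content = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in line.split("\t")]
            if first_content:
                first_content = False
                if any(c.lower() in _HEADER_TOKENS for c in cells):
                    continue
            yield lineno, cells


def read_edge_list(path: str | Path,
                   evidence_filter: set[str] | None = None) -> nx.Graph:
    """Read a tab-separated protein interaction list into a simple graph.

    Parameters
    ----------
    path:
        TSV file with rows ``protein_a<TAB>protein_b[<TAB>source[<TAB>evidence]]``.
        ``#``-prefixed lines are comments; a header line is detected by known
        column-name tokens; a single-column row declares an isolated node.
    evidence_filter:
        If given, rows whose evidence tag (4th column) is not in this set are
        dropped *before* deduplication.  Rows without an evidence column never
        pass the filter.

    Returns
    -------
    networkx.Graph
        Simple undirected graph.  Duplicate pairs (in either order) are
        merged; self-loops are dropped (their count is logged).

    Raises
    ------
    ValueError
        On malformed rows (0 or more than 4 columns after splitting) or if no
        edge and no node survives filtering.
    """
    net = nx.Graph(name=Path(path).stem)
    n_loops = 0
    n_rows = 0
    for lineno, cells in _rows(path):
        if len(cells) > _MAX_COLUMNS or not cells[0]:
            raise ValueError(
                f"{path}: malformed row at line {lineno}: expected 1-4 "
                f"tab-separated columns, got {len(cells)}")
        if len(cells) == 1:
            net.add_node(cells[0])
            continue
        a, b = cells[0], cells[1]
        if not b:
            raise ValueError(f"{path}: malformed row at line {lineno}: empty ID")
        if evidence_filter is not None:
            evidence = cells[3] if len(cells) >= 4 else None
            if evidence not in evidence_filter:
                continue
        n_rows += 1
        if a == b:
            n_loops += 1
            continue
        net.add_edge(a, b)
    if n_loops:
        logger.info("read_edge_list(%s): dropped %d self-loop rows", path, n_loops)
    if evidence_filter is not None and net.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty network after evidence filtering")
    logger.info("read_edge_list(%s): %d nodes, %d edges from %d interaction rows",
                path, net.number_of_nodes(), net.number_of_edges(), n_rows)
    return net


def read_regulations(path: str | Path) -> RegulationTable:
    """Read a ``mirna<TAB>target[<TAB>source]`` table, collapsing duplicates."""
    table = RegulationTable()
    for lineno, cells in _rows(path):
        if len(cells) < 2 or len(cells) > 3 or not cells[0] or not cells[1]:
            raise ValueError(
                f"{path}: malformed row at line {lineno}: expected "
                f"mirna<TAB>target[<TAB>source]")
        table.add(cells[0], cells[1], cells[2] if len(cells) == 3 else None)
    if len(table) == 0:
        logger.warning("read_regulations(%s): empty table", path)
    else:
        logger.info("read_regulations(%s): %d records", path, len(table))
    return table


def write_regulations(table: RegulationTable, path: str | Path) -> None:
    """Write a regulation table as sorted ``mirna<TAB>target[<TAB>source]`` rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\ttarget\tsource\n")
        for mirna, target in sorted(table.pairs):
            src = ";".join(sorted(table.sources.get((mirna, target), ())))
            fh.write(f"{mirna}\t{target}\t{src}\n")


def write_network(net: nx.Graph, path: str | Path, format: str = "tsv") -> None:
    """Write a network as a TSV edge list or GraphML.

    Round-trip contract: reading the written file back returns the identical
    (node set, edge set); isolated nodes survive both formats.
    """
    if format in ("tsv", "tsv-edgelist"):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in net.edges):
                fh.write(f"{a}\t{b}\n")
            for node in sorted(nx.isolates(net)):
                fh.write(f"{node}\n")
    elif format == "graphml":
        # canonical node/edge order so identical networks serialize identically
        canon = nx.Graph(name=net.graph.get("name", ""))
        canon.add_nodes_from(sorted(net.nodes))
        canon.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
        nx.write_graphml(canon, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path, format: str | None = None) -> nx.Graph:
    """Read a network written by :func:`write_network` (format by extension)."""
    if format is None:
        format = "graphml" if str(path).endswith(".graphml") else "tsv"
    if format == "graphml":
        g = nx.read_graphml(path)
        net = nx.Graph(name=Path(path).stem)
        net.add_nodes_from(g.nodes)
        net.add_edges_from((a, b) for a, b in g.edges if a != b)
        return net
    return read_edge_list(path)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, nx.Graph):
        return {"nodes": sorted(obj.nodes),
                "edges": sorted([sorted(e) for e in obj.edges])}
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"cannot serialize field of type {type(obj).__name__}")


def write_report(obj, path: str | Path) -> None:
    """Serialize a pipeline result object to JSON at full float precision.

    Floats are written with Python's shortest-round-trip repr, so parsing the
    file back reproduces every value bit for bit.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
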