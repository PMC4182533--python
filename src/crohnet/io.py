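"""Readers and writers for the pipeline's external artifacts.

All formats are plain text, tab-delimited unless noted:

* edge list — two columns of identifiers, one interaction per line
* gene set — one identifier per line
* ranked list — TSV with header ``id  score  p_value``
* annotations — GMT dialect (``name<TAB>description<TAB>member...``)
* DE table — TSV with header ``id  adj_p``

Graphs are simplified on input: self-interactions are dropped (they distort
degree, clustering and motif statistics) and duplicate records collapsed; a
:class:`~crohnet.types.LoadSummary` reports what was removed. Identifiers are
case-sensitive opaque strings — no ID mapping is performed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx

from .types import AnnotationMap, DETable, GeneSet, LoadSummary, RankedList, ValidationError


class ParseError(ValueError):
    """Malformed input line, reported with its line number."""


def read_edge_list(
    path: str | Path,
    keep_self_loops: bool = False,
    tolerant: bool = False,
) -> tuple[nx.Graph, LoadSummary]:
    """Read a two-column edge list into a simplified undirected graph.

    Parameters
    ----------
    path:
        Delimited text file with at least two identifier columns per line
        (tabs or any whitespace). Blank lines are ignored.
    keep_self_loops:
        Retain self-interactions. They count toward degree but are excluded
        from clustering and motif computations downstream.
    tolerant:
        If set, lines with fewer than two fields are counted as malformed and
        skipped instead of raising :class:`ParseError`.

    Returns
    -------
    (graph, summary):
        The simplified graph and a load summary whose counts partition the
        input lines (kept + dropped self-loops + collapsed duplicates +
        malformed).
    """
    net = nx.Graph()
    summary = LoadSummary()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                if tolerant:
                    summary.dropped_malformed += 1
                    continue
                raise ParseError(f"{path}: line {lineno}: expected >=2 fields, got {len(fields)}")
            a, b = fields[0], fields[1]
            if a == b and not keep_self_loops:
                summary.dropped_self_loops += 1
                continue
            if net.has_edge(a, b):
                summary.dropped_duplicates += 1
                continue
            net.add_edge(a, b)
            summary.kept += 1
    return net, summary


def write_edge_list(net: nx.Graph, path: str | Path, node_sidecar: str | Path | None = None) -> None:
    """Write a graph as a sorted two-column TSV.

    Edge endpoints are emitted in lexicographic order and lines sorted, so the
    output is deterministic and ``read_edge_list(write_edge_list(g))`` is the
    identity on simplified graphs. Isolated nodes cannot be encoded in an edge
    list; pass ``node_sidecar`` to write the full node list alongside.
    """
    lines = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")
    if node_sidecar is not None:
        with open(node_sidecar, "w", encoding="utf-8") as fh:
            for n in sorted(net.nodes()):
                fh.write(f"{n}\n")


def read_gene_set(path: str | Path, label: str | None = None) -> GeneSet:
    """Read a one-identifier-per-line gene set; duplicates collapse with a warning."""
    seen: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            g = raw.strip()
            if g:
                seen.append(g)
    if len(seen) != len(set(seen)):
        warnings.warn(f"{path}: duplicate identifiers collapsed", stacklevel=2)
    return GeneSet(label or Path(path).stem, seen)


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes.members):
            fh.write(f"{g}\n")


def read_ranked_list(path: str | Path) -> RankedList:
    """Read a ``id score p_value`` TSV (header required) into a RankedList."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return RankedList([])
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            rows.append((fields[0], float(fields[1]), float(fields[2])))
    return RankedList(rows)


def write_ranked_list(ranking: RankedList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tscore\tp_value\n")
        for g, s, p in ranking.entries:
            fh.write(f"{g}\t{s:.10g}\t{p:.10g}\n")


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    classes: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT needs name, description, >=1 member")
            name = fields[0]
            if name in classes:
                raise ValidationError(f"{path}: duplicate class name {name!r}")
            classes[name] = {g for g in fields[2:] if g}
    return AnnotationMap(classes)


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(annotations.classes):
            members = "\t".join(sorted(annotations.classes[name]))
            fh.write(f"{name}\t-\t{members}\n")


def read_de_table(path: str | Path) -> DETable:
    """Read a ``id adj_p`` TSV (header required) into a DETable."""
    rows: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return DETable({})
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            g = fields[0]
            if g in rows:
                warnings.warn(f"{path}: duplicate identifier {g!r} collapsed", stacklevel=2)
            rows[g] = float(fields[1])
    return DETable(rows)


def write_de_table(table: DETable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tadj_p\n")
        for g in sorted(table.rows):
            fh.write(f"{g}\t{table.rows[g]:.10g}\n")
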