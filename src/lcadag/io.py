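"""Reading and writing DAGs, cluster systems, and undirected graphs.

The primary interchange format is a small canonical JSON document (DAGs are
generally not trees, so Newick is unsuitable).  Serialization is canonical
-- vertices and edges sorted -- so semantically equal DAGs produce
byte-identical files.  A plain TSV edge list is supported as a secondary
format: one ``parent<TAB>child`` line per edge, with isolated vertices
declared on single-column lines.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .dag_core import DAG, ClusterSystem
from .errors import FileFormatError, GraphValidationError, NotADAGError
from .synthetic import UndirectedGraph

__all__ = [
    "DAG_FORMAT",
    "dag_to_document",
    "dag_from_document",
    "read_dag",
    "write_dag",
    "dumps_dag",
    "read_clusters",
    "write_clusters",
    "read_undirected_graph",
]

DAG_FORMAT = "lcadag/dag/1"


def dag_to_document(G: DAG, metadata: Optional[Dict] = None) -> Dict:
    doc: Dict = {
        "format": DAG_FORMAT,
        "vertices": sorted(G.vertices),
        "edges": sorted([u, v] for u, v in G.edges),
    }
    if metadata:
        doc["metadata"] = metadata
    return doc


def dag_from_document(doc: Dict, context: str = "<document>") -> DAG:
    if not isinstance(doc, dict) or "vertices" not in doc or "edges" not in doc:
        raise FileFormatError(
            f"{context}: expected a JSON object with 'vertices' and 'edges'"
        )
    try:
        edges = [tuple(e) for e in doc["edges"]]
        if any(len(e) != 2 for e in edges):
            raise FileFormatError(f"{context}: every edge must be a [parent, child] pair")
        return DAG(doc["vertices"], edges)
    except GraphValidationError as exc:
        raise type(exc)(f"{context}: {exc}") from None


def dumps_dag(G: DAG, metadata: Optional[Dict] = None) -> str:
    """Canonical JSON text for G (sorted keys, sorted vertices/edges)."""
    return json.dumps(dag_to_document(G, metadata), sort_keys=True, indent=2) + "\n"


def _infer_format(path: Union[str, Path], format: Optional[str]) -> str:
    if format is not None:
        if format not in ("json", "tsv"):
            raise ValueError(f"unknown format {format!r}")
        return format
    return "tsv" if str(path).endswith((".tsv", ".txt")) else "json"


def write_dag(
    G: DAG,
    path: Union[str, Path],
    format: Optional[str] = None,
    metadata: Optional[Dict] = None,
) -> None:
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "json":
        path.write_text(dumps_dag(G, metadata))
        return
    lines = [f"{u}\t{v}" for u, v in sorted(G.edges)]
    touched = {x for e in G.edges for x in e}
    lines.extend(sorted(G.vertices - touched))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _read_tsv(text: str, context: str) -> DAG:
    vertices = set()
    edges = []
    edge_line: Dict[Tuple[str, str], int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            vertices.add(fields[0].strip())
        elif len(fields) == 2:
            u, v = fields[0].strip(), fields[1].strip()
            if not u or not v:
                raise FileFormatError(f"{context}:{lineno}: empty vertex label")
            vertices.update((u, v))
            edges.append((u, v))
            edge_line.setdefault((u, v), lineno)
        else:
            raise FileFormatError(
                f"{context}:{lineno}: expected 1 or 2 tab-separated fields"
            )
    if not vertices:
        raise FileFormatError(f"{context}: no vertices declared")
    try:
        return DAG(vertices, edges)
    except NotADAGError:
        cycle_lines = _cycle_lines(vertices, edges, edge_line)
        raise NotADAGError(
            f"{context}: not a DAG: directed cycle through edges on lines {cycle_lines}"
        ) from None
    except GraphValidationError as exc:
        raise type(exc)(f"{context}: {exc}") from None


def _cycle_lines(vertices, edges, edge_line) -> List[int]:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges)
    cycle = nx.find_cycle(g)
    return sorted(edge_line[(u, v)] for u, v, *_ in cycle)


def read_dag(path: Union[str, Path], format: Optional[str] = None) -> DAG:
    fmt = _infer_format(path, format)
    path = Path(path)
    text = path.read_text()
    if fmt == "tsv":
        return _read_tsv(text, str(path))
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FileFormatError(f"{path}: malformed JSON: {exc}") from None
    return dag_from_document(doc, context=str(path))


def write_clusters(system: ClusterSystem, path: Union[str, Path]) -> None:
    """One cluster per line as comma-separated sorted labels; lines sorted."""
    lines = sorted(
        ",".join(sorted(c)) for c in system.clusters
    )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_clusters(path: Union[str, Path]) -> ClusterSystem:
    path = Path(path)
    text = path.read_text()
    raw_lines = text.splitlines()
    clusters = set()
    seen = set()
    for lineno, raw in enumerate(raw_lines, start=1):
        if not raw.strip():
            if lineno == len(raw_lines):
                continue  # tolerate a trailing blank line
            raise FileFormatError(f"{path}:{lineno}: empty cluster line")
        labels = [x.strip() for x in raw.split(",")]
        if any(not x for x in labels):
            raise FileFormatError(f"{path}:{lineno}: empty label in cluster line")
        c = frozenset(labels)
        if c in seen:
            warnings.warn(f"{path}:{lineno}: duplicate cluster line collapsed")
        seen.add(c)
        clusters.add(c)
    if not clusters:
        raise FileFormatError(f"{path}: no clusters in file")
    ground = frozenset().union(*clusters)
    return ClusterSystem(ground, frozenset(clusters))


def read_undirected_graph(path: Union[str, Path]) -> UndirectedGraph:
    """Undirected graph as a TSV edge list (isolated vertices on single lines)."""
    path = Path(path)
    vertices = set()
    edges = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) == 1:
            vertices.add(fields[0].strip())
        elif len(fields) == 2:
            u, v = fields[0].strip(), fields[1].strip()
            vertices.update((u, v))
            edges.add(frozenset((u, v)))
        else:
            raise FileFormatError(f"{path}:{lineno}: expected 1 or 2 fields")
    return UndirectedGraph(frozenset(vertices), frozenset(edges))
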