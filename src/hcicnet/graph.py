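"""Undirected simple-graph model, file I/O and summary statistics.

Graphs are plain :class:`networkx.Graph` objects with string node labels.
Loaders normalize away self-loops and duplicate edges (with a logged
warning), because every metric in this package assumes a simple graph
(``a_ii = 0``, ``a_ij = a_ji``).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import scipy.io

log = logging.getLogger(__name__)

FORMATS = ("edgelist", "matrix-market", "graphml")


class GraphFormatError(ValueError):
    """Raised for malformed graph input (carries a line number when known)."""


@dataclass(frozen=True)
class GraphSummary:
    """Whole-graph statistics: N, M, <k>, k_max, average clustering, density."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    k_max: int
    c_avg: float
    density: float


def _normalize(g: nx.Graph) -> nx.Graph:
    loops = list(nx.selfloop_edges(g))
    if loops:
        log.warning("dropping %d self-loop(s)", len(loops))
        g.remove_edges_from(loops)
    return g


def _parse_edgelist(lines: Iterable[str], nodes: Iterable[str] | None = None) -> nx.Graph:
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(str(n) for n in nodes)
    seen = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line[0] in "#%":
            continue
        parts = line.split()
        if len(parts) < 2:
            raise GraphFormatError(f"line {lineno}: expected two node labels, got {line!r}")
        u, v = parts[0], parts[1]
        if g.has_edge(u, v):
            seen += 1
        g.add_edge(u, v)
    if seen:
        log.warning("collapsed %d duplicate edge(s)", seen)
    return _normalize(g)


def _parse_matrix_market(stream) -> nx.Graph:
    try:
        mat = scipy.io.mmread(stream)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise GraphFormatError(f"malformed Matrix Market input: {exc}") from exc
    coo = mat.tocoo()
    g = nx.Graph()
    # 1-based labels per the Matrix Market convention, kept as strings
    g.add_nodes_from(str(i + 1) for i in range(max(coo.shape)))
    for i, j in zip(coo.row, coo.col):
        if i != j:
            g.add_edge(str(i + 1), str(j + 1))
    return g


def load_graph(source, format: str = "edgelist", nodes: Iterable[str] | None = None) -> nx.Graph:
    """Load an undirected simple graph from a path or text stream.

    Parameters
    ----------
    source
        File path, or an open text stream.
    format
        One of ``edgelist``, ``matrix-market``, ``graphml``.
    nodes
        Optional explicit node roster (edgelist only) so isolated nodes
        survive a round trip.
    """
    if format not in FORMATS:
        raise GraphFormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "edgelist":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                return _parse_edgelist(fh, nodes)
        return _parse_edgelist(source, nodes)
    if format == "matrix-market":
        return _parse_matrix_market(source)
    g = nx.read_graphml(source)
    if g.is_directed():
        raise GraphFormatError("GraphML input must be an undirected graph")
    g = nx.relabel_nodes(nx.Graph(g), {n: str(n) for n in g.nodes})
    return _normalize(g)


def save_edgelist(g: nx.Graph, target) -> None:
    """Write one edge per line (two whitespace-separated labels)."""
    own = isinstance(target, (str, Path))
    fh = open(target, "w") if own else target
    try:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u} {v}\n")
    finally:
        if own:
            fh.close()


def loads_edgelist(text: str, nodes: Iterable[str] | None = None) -> nx.Graph:
    """Parse an edge list from a string (convenience for fixtures/tests)."""
    return _parse_edgelist(io.StringIO(text), nodes)


def remove_nodes(g: nx.Graph, victims: Iterable[str]) -> nx.Graph:
    """Return a copy of ``g`` without ``victims`` and their incident edges."""
    victims = set(victims)
    unknown = victims - set(g.nodes)
    if unknown:
        raise KeyError(f"unknown node label(s): {sorted(unknown)}")
    h = g.copy()
    h.remove_nodes_from(victims)
    return h


def connected_components(g: nx.Graph) -> list[set[str]]:
    """Connected components as a partition of the node labels."""
    return [set(c) for c in nx.connected_components(g)]


def graph_summary(g: nx.Graph) -> GraphSummary:
    """Basic attributes: N, M, mean degree 2M/N, k_max, C_avg, density.

    Nodes of degree < 2 contribute clustering 0 to ``c_avg`` (the
    networkx convention).
    """
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("no statistics on an empty graph")
    return GraphSummary(
        n_nodes=n,
        n_edges=m,
        mean_degree=2 * m / n,
        k_max=max(dict(g.degree).values()),
        c_avg=nx.average_clustering(g),
        density=0.0 if n == 1 else 2 * m / (n * (n - 1)),
    )
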