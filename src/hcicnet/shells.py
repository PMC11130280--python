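"""Global node-importance metrics: K-shell peeling, IKS, tenacity, HTGC.

K-shell decomposition peels the graph from the boundary inward: take the
current minimum degree KS, recursively delete every node whose residual
degree is <= KS (in sweeps), label the deleted nodes KS, repeat. The
improved shell value refines ties within a layer by the node's original
degree:

    IKS_i = KS_i + k_i / (k_max(layer) + 1) * (KS_next - KS_i)

so KS_i <= IKS_i < KS_next. The per-node tenacity adapts a classic
graph-vulnerability measure: T_{G,i} = (1 + τ(G - i)) / ω(G - i), where
τ is the largest-component size and ω the component count after deleting
node i — small T means deleting i shatters the graph. The hierarchical
tenacity global coefficient divides the two: HTGC_i = T_{G,i} / IKS_i
(low = globally important).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .scores import HIGH, LOW, ScoreTable

#: Exhaustive-enumeration guard for the edge-tenacity oracle.
EDGE_TENACITY_MAX_EDGES = 16


@dataclass(frozen=True)
class ShellDecomposition:
    """Result of K-shell peeling with full bookkeeping.

    ks
        node -> shell value KS_i (isolated nodes get 0).
    peel_iteration
        node -> 1-based index of the outer KS round that removed it.
    strip_order
        node -> 1-based sweep index l_i *within its shell*; nodes removed
        in the same recursive sweep share the index (within-sweep order is
        deliberately not broken).
    layer_sweeps
        shell value -> number of sweeps l_max in that shell.
    layer_max_degree
        shell value -> maximum ORIGINAL degree among the layer's nodes.
    layer_next
        shell value -> KS_next: the smallest shell value present that is
        larger, or KS + 1 for the deepest layer.
    """

    ks: Mapping[str, int] = field(repr=False)
    peel_iteration: Mapping[str, int] = field(repr=False)
    strip_order: Mapping[str, int] = field(repr=False)
    layer_sweeps: Mapping[int, int]
    layer_max_degree: Mapping[int, int]
    layer_next: Mapping[int, int]

    def to_csv(self, target, g: nx.Graph) -> None:
        own = isinstance(target, str)
        fh = open(target, "w") if own else target
        try:
            fh.write("node,ks,iks,peel_iteration,strip_order\n")
            iks_t = iks(g, self)
            for n in sorted(self.ks):
                fh.write(
                    f"{n},{self.ks[n]},{iks_t[n]!r},"
                    f"{self.peel_iteration[n]},{self.strip_order[n]}\n"
                )
        finally:
            if own:
                fh.close()


def kshell_decompose(g: nx.Graph) -> ShellDecomposition:
    """Standard k-core peeling, recording shells, rounds and sweep order."""
    ks: dict[str, int] = {}
    peel: dict[str, int] = {}
    strip: dict[str, int] = {}
    layer_sweeps: dict[int, int] = {}
    layer_maxdeg: dict[int, int] = {}
    orig_degree = dict(g.degree)

    h = g.copy()
    round_no = 0
    while h.number_of_nodes():
        round_no += 1
        shell = min(dict(h.degree).values())
        sweep = 0
        while True:
            batch = [n for n, d in h.degree if d <= shell]
            if not batch:
                break
            sweep += 1
            for n in batch:
                ks[n] = shell
                peel[n] = round_no
                strip[n] = sweep
            h.remove_nodes_from(batch)
        layer_sweeps[shell] = sweep
        layer_maxdeg[shell] = max(orig_degree[n] for n in ks if ks[n] == shell)

    shells = sorted(layer_sweeps)
    layer_next = {
        s: next((t for t in shells if t > s), s + 1) for s in shells
    }
    return ShellDecomposition(ks, peel, strip, layer_sweeps, layer_maxdeg, layer_next)


def kshell_table(g: nx.Graph, d: ShellDecomposition | None = None) -> ScoreTable:
    d = kshell_decompose(g) if d is None else d
    return ScoreTable("kshell", {n: float(v) for n, v in d.ks.items()}, HIGH)


def iks(g: nx.Graph, d: ShellDecomposition | None = None) -> ScoreTable:
    """Improved K-shell value (high = important), using original degrees."""
    d = kshell_decompose(g) if d is None else d
    out = {}
    for n in g.nodes:
        s = d.ks[n]
        out[n] = s + g.degree(n) / (d.layer_max_degree[s] + 1) * (d.layer_next[s] - s)
    return ScoreTable("iks", out, HIGH)


def node_tenacity(g: nx.Graph, i: str) -> float:
    """T_{G,i} = (1 + τ(G - i)) / ω(G - i); low = removal shatters the graph."""
    if g.number_of_nodes() == 1:
        raise ValueError("node tenacity is undefined on a single-node graph")
    h = g.copy()
    h.remove_node(i)
    comps = [len(c) for c in nx.connected_components(h)]
    return (1 + max(comps)) / len(comps)


def tenacity_table(g: nx.Graph) -> ScoreTable:
    return ScoreTable("tenacity", {i: node_tenacity(g, i) for i in g.nodes}, LOW)


def _disconnects(g: nx.Graph, edges: Iterable[tuple[str, str]]) -> bool:
    h = g.copy()
    h.remove_edges_from(edges)
    return not nx.is_connected(h)


def is_cut_set(g: nx.Graph, s: Iterable[tuple[str, str]]) -> bool:
    """True iff deleting ``s`` disconnects ``g`` and no proper subset does.

    Minimality only needs the maximal proper subsets: if any smaller
    subset disconnected the graph, so would some superset of it of size
    ``len(s) - 1`` (removing more edges never reconnects).
    """
    if not nx.is_connected(g):
        raise ValueError("cut sets are defined on connected graphs")
    s = [tuple(e) for e in s]
    for u, v in s:
        if not g.has_edge(u, v):
            raise ValueError(f"({u!r}, {v!r}) is not an edge of the graph")
    if not _disconnects(g, s):
        return False
    return not any(
        _disconnects(g, s[:k] + s[k + 1:]) for k in range(len(s))
    )


def edge_tenacity_bruteforce(g: nx.Graph) -> float:
    """Exact edge-set tenacity min over cut sets A of (|A| + τ) / ω.

    Conceptual oracle only: exhaustive over all edge subsets, guarded at
    ``EDGE_TENACITY_MAX_EDGES`` edges (the minimization is NP-hard).
    """
    if not nx.is_connected(g):
        raise ValueError("edge tenacity is defined on connected graphs")
    m = g.number_of_edges()
    if m > EDGE_TENACITY_MAX_EDGES:
        raise ValueError(
            f"{m} edges exceeds the brute-force guard "
            f"({EDGE_TENACITY_MAX_EDGES}); use node_tenacity instead"
        )
    edges = list(g.edges)
    best = None
    for r in range(1, m + 1):
        for cand in itertools.combinations(edges, r):
            if not is_cut_set(g, cand):
                continue
            h = g.copy()
            h.remove_edges_from(cand)
            comps = [len(c) for c in nx.connected_components(h)]
            val = (r + max(comps)) / len(comps)
            best = val if best is None else min(best, val)
    if best is None:
        raise ValueError("graph has no cut set")
    return best


def htgc(g: nx.Graph) -> ScoreTable:
    """Hierarchical tenacity global coefficient T_{G,i} / IKS_i (low = important).

    Isolated nodes have IKS = 0 (shell 0, degree 0), where the quotient
    diverges; they are assigned the largest finite HTGC in the table —
    i.e. they tie for least important — so score tables stay total on
    fragmented graphs.
    """
    iks_t = iks(g)
    out: dict[str, float] = {}
    isolated: list[str] = []
    for i in g.nodes:
        t = node_tenacity(g, i)
        if iks_t[i] == 0:
            isolated.append(i)
        else:
            out[i] = t / iks_t[i]
    if isolated:
        logging.getLogger(__name__).warning(
            "%d isolated node(s) assigned the least-important HTGC", len(isolated)
        )
        cap = max(out.values(), default=1.0)
        for i in isolated:
            out[i] = cap
    return ScoreTable("htgc", out, LOW)
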