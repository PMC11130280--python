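"""Local node-importance metrics built on structural-hole theory.

The chain is: investment ratio p_ij -> Burt's network constraint
coefficient NCC -> neighborhood-overlap (weak-tie) indices (Salton,
Jaccard) -> per-edge weak-connection coefficient w -> the weak-tie
weighted constraint coefficient WNCC.

NCC_i = sum over neighbors j of (p_ij + sum over common neighbors l of
p_il * p_lj)^2, where p_ij = a_ij / k_i is the share of i's links spent
on j. Low constraint = many non-redundant contacts = strong broker =
important node. WNCC multiplies each squared term by w_ij so that weak
ties — edges whose endpoints share little neighborhood — lower the
constraint of the nodes that hold them:

    w_ij = (S_ij * sqrt((k_i - 1)(k_j - 1)) + 1) / (|Γ(i) ∪ Γ(j)| - 1)

with S_ij the Salton (cosine) overlap of the two open neighborhoods.
The denominator subtracts exactly 1 from the plain union of the two
open neighborhoods (which, for adjacent i and j, contains both
endpoints); this literal convention reproduces the published worked
example exactly.
"""

from __future__ import annotations

import logging
import math

import networkx as nx

from .scores import LOW, ScoreTable

log = logging.getLogger(__name__)

#: Policy value for the constraint of an isolated node: the leaf /
#: maximal-constraint value, so score tables stay total on fragmented graphs.
ISOLATED_CONSTRAINT = 1.0


def investment_ratio(g: nx.Graph, i: str, j: str) -> float:
    """p_ij = a_ij / k_i — share of i's links invested in j."""
    k = g.degree(i)
    if k == 0:
        raise ZeroDivisionError(f"investment ratio undefined for isolated node {i!r}")
    return (1.0 if g.has_edge(i, j) else 0.0) / k


def _constraint_term(g: nx.Graph, i: str, j: str) -> float:
    """p_ij plus the indirect investment routed through common neighbors."""
    p = investment_ratio
    return p(g, i, j) + sum(p(g, i, l) * p(g, l, j) for l in nx.common_neighbors(g, i, j))


def ncc(g: nx.Graph, i: str) -> float:
    """Burt's network constraint coefficient of node ``i`` (low = important)."""
    if g.degree(i) == 0:
        log.warning("isolated node %r: NCC set to policy value %s", i, ISOLATED_CONSTRAINT)
        return ISOLATED_CONSTRAINT
    return sum(_constraint_term(g, i, j) ** 2 for j in g[i])


def ncc_table(g: nx.Graph) -> ScoreTable:
    return ScoreTable("ncc", {i: ncc(g, i) for i in g.nodes}, LOW)


def salton(g: nx.Graph, i: str, j: str) -> float:
    """Cosine overlap of neighborhoods: |Γ(i) ∩ Γ(j)| / sqrt(k_i k_j)."""
    ki, kj = g.degree(i), g.degree(j)
    if ki == 0 or kj == 0:
        raise ZeroDivisionError(f"Salton index undefined for isolated endpoint of ({i!r}, {j!r})")
    return len(set(g[i]) & set(g[j])) / math.sqrt(ki * kj)


def jaccard(g: nx.Graph, i: str, j: str) -> float:
    """|Γ(i) ∩ Γ(j)| / |Γ(i) ∪ Γ(j)|."""
    union = set(g[i]) | set(g[j])
    if not union:
        raise ZeroDivisionError(f"Jaccard index undefined: both {i!r} and {j!r} are isolated")
    return len(set(g[i]) & set(g[j])) / len(union)


def weak_connection(g: nx.Graph, i: str, j: str) -> float:
    """Weak-connection coefficient w_ij of the *edge* (i, j).

    Defined only for adjacent nodes. Symmetric and strictly positive;
    small shared neighborhoods (weak ties) yield small w.
    """
    if not g.has_edge(i, j):
        raise ValueError(f"weak_connection requires adjacent nodes; ({i!r}, {j!r}) is not an edge")
    s = salton(g, i, j)
    num = s * math.sqrt((g.degree(i) - 1) * (g.degree(j) - 1)) + 1.0
    den = len(set(g[i]) | set(g[j])) - 1
    return num / den


def wncc(g: nx.Graph) -> ScoreTable:
    """Weak-tie weighted constraint coefficient for every node (low = important)."""
    out: dict[str, float] = {}
    for i in g.nodes:
        if g.degree(i) == 0:
            log.warning("isolated node %r: WNCC set to policy value %s", i, ISOLATED_CONSTRAINT)
            out[i] = ISOLATED_CONSTRAINT
            continue
        out[i] = sum(
            weak_connection(g, i, j) * _constraint_term(g, i, j) ** 2 for j in g[i]
        )
    return ScoreTable("wncc", out, LOW)
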