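"""Classic benchmark rankers: DC, CI, WL, DWT, KPD, INCC and random.

These are the comparison algorithms for the composite HCIC ranker;
K-shell itself lives in :mod:`hcicnet.shells`.
"""

from __future__ import annotations

import logging
import random as _random

import networkx as nx

from .local import investment_ratio, salton
from .scores import HIGH, LOW, ScoreTable
from .shells import ShellDecomposition, kshell_decompose

log = logging.getLogger(__name__)


def degree_centrality(g: nx.Graph) -> ScoreTable:
    """DC_i = k_i."""
    return ScoreTable("dc", {n: float(k) for n, k in g.degree}, HIGH)


def collective_influence(g: nx.Graph, l: int = 2) -> ScoreTable:
    """CI_i = (k_i - 1) * sum of (k_j - 1) over nodes within distance < l.

    The ball excludes i itself. Default radius l=2 (nearest neighbors).
    """
    if l < 1:
        raise ValueError("CI radius l must be >= 1")
    out = {}
    for i in g.nodes:
        ball = nx.single_source_shortest_path_length(g, i, cutoff=l - 1)
        out[i] = (g.degree(i) - 1) * sum(
            g.degree(j) - 1 for j in ball if j != i
        )
    return ScoreTable("ci", out, HIGH)


def wl_score(g: nx.Graph) -> ScoreTable:
    """WL_i = sum over neighbors j of k_i * k_j."""
    return ScoreTable(
        "wl",
        {i: float(sum(g.degree(i) * g.degree(j) for j in g[i])) for i in g.nodes},
        HIGH,
    )


def dwt_score(g: nx.Graph) -> ScoreTable:
    """DWT_i = sum over neighbors j of ((1 + S_ij) / k_i)^2.

    A constraint-style sum (low = important). Isolated nodes get the
    maximal-constraint policy value 1.0.
    """
    out = {}
    for i in g.nodes:
        k = g.degree(i)
        if k == 0:
            log.warning("isolated node %r: DWT set to policy value 1.0", i)
            out[i] = 1.0
            continue
        out[i] = sum(((1 + salton(g, i, j)) / k) ** 2 for j in g[i])
    return ScoreTable("dwt", out, LOW)


def kpd_score(g: nx.Graph, d: ShellDecomposition | None = None) -> ScoreTable:
    """KPD_i = KS_i + k_i + l_i / (l_max + 1), sweep-level stripping order."""
    d = kshell_decompose(g) if d is None else d
    out = {
        i: d.ks[i] + g.degree(i) + d.strip_order[i] / (d.layer_sweeps[d.ks[i]] + 1)
        for i in g.nodes
    }
    return ScoreTable("kpd", out, HIGH)


def incc_score(g: nx.Graph) -> ScoreTable:
    """INCC_i = sum over neighbors j of [p_ij + sum over common neighbors k
    of i and j of p_ik] (the inner sum nested inside the outer one)."""
    out = {}
    for i in g.nodes:
        if g.degree(i) == 0:
            out[i] = 0.0
            continue
        out[i] = sum(
            investment_ratio(g, i, j)
            + sum(investment_ratio(g, i, k) for k in nx.common_neighbors(g, i, j))
            for j in g[i]
        )
    return ScoreTable("incc", out, HIGH)


def random_score(g: nx.Graph, seed: int) -> ScoreTable:
    """I.i.d. uniform scores from a seeded generator; all values distinct."""
    rng = _random.Random(seed)
    out: dict[str, float] = {}
    used: set[float] = set()
    for i in sorted(g.nodes):
        v = rng.random()
        while v in used:  # collisions have probability ~0 but cost nothing
            v = rng.random()
        used.add(v)
        out[i] = v
    return ScoreTable("random", out, HIGH)
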