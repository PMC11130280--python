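"""Targeted-attack harness and the four evaluation indicators.

Protocol (static): rank the intact graph once; at each removal fraction
q delete the top ``count(q, N)`` nodes from the ORIGINAL graph and
measure the remainder:

* P_Subset — largest-component size R as a percentage of the original N;
* P_Edges  — remaining edge count E as a percentage of the original M;
* S        — susceptibility-style sensitivity, the size-weighted second
  moment of the non-giant component sizes: sum over s < σ of n_s s² / N,
  with σ = giant-component size by default;
* m        — monotonicity of a score table, (r - 1)/(N - 1) · 100% with
  r the number of distinct score values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .composite import RankingResult
from .scores import ScoreTable

DEFAULT_FRACTIONS = tuple(i / 100 for i in range(51))  # 0 .. 0.5 step 0.01


@dataclass(frozen=True)
class AttackCurve:
    metric_name: str
    fractions: tuple[float, ...]
    removed: tuple[int, ...]
    p_subset: tuple[float, ...]  # percent
    p_edges: tuple[float, ...]  # percent
    sensitivity: tuple[float, ...]
    removal_order: tuple[str, ...] = field(repr=False)
    sigma_rule: str = "giant"
    count_rule: str = "floor"

    def to_rows(self) -> list[dict]:
        return [
            {
                "method": self.metric_name,
                "fraction": f,
                "removed": r,
                "p_subset": ps,
                "p_edges": pe,
                "sensitivity": s,
            }
            for f, r, ps, pe, s in zip(
                self.fractions, self.removed, self.p_subset, self.p_edges, self.sensitivity
            )
        ]

    def to_csv(self, target) -> None:
        own = isinstance(target, str)
        fh = open(target, "w") if own else target
        try:
            fh.write("method,fraction,removed,p_subset,p_edges,sensitivity\n")
            for row in self.to_rows():
                fh.write(
                    f"{row['method']},{row['fraction']!r},{row['removed']},"
                    f"{row['p_subset']!r},{row['p_edges']!r},{row['sensitivity']!r}\n"
                )
        finally:
            if own:
                fh.close()

    def to_json(self, target) -> None:
        own = isinstance(target, str)
        fh = open(target, "w") if own else target
        try:
            json.dump(
                {"sigma_rule": self.sigma_rule, "count_rule": self.count_rule,
                 "rows": self.to_rows()},
                fh, indent=1,
            )
        finally:
            if own:
                fh.close()


@dataclass(frozen=True)
class MonotonicityResult:
    m: float  # percent
    r: int
    n: int


def removal_count(q: float, n: int, rule: str = "floor") -> int:
    """Number of nodes removed at fraction q; floor(qN) or round(qN)."""
    if rule == "floor":
        return math.floor(q * n + 1e-9)
    if rule == "round":
        return round(q * n)
    raise ValueError(f"unknown removal-count rule {rule!r}")


def max_connectivity(g_original: nx.Graph, g_remaining: nx.Graph) -> float:
    """P_Subset = R / N * 100%, R the largest remaining component (0 if empty)."""
    n = g_original.number_of_nodes()
    if g_remaining.number_of_nodes() == 0:
        return 0.0
    r = max(len(c) for c in nx.connected_components(g_remaining))
    return r / n * 100.0


def remaining_edges(g_original: nx.Graph, g_remaining: nx.Graph) -> float:
    """P_Edges = E / M * 100%."""
    m = g_original.number_of_edges()
    if m == 0:
        raise ZeroDivisionError("P_Edges undefined on an edgeless original graph")
    return g_remaining.number_of_edges() / m * 100.0


def sensitivity(g_remaining: nx.Graph, n_original: int, sigma: int | str = "giant") -> float:
    """S = sum over component sizes s < σ of n_s * s^2 / N.

    ``sigma='giant'`` excludes the largest remaining component (standard
    susceptibility); an integer fixes the threshold instead.
    """
    sizes = [len(c) for c in nx.connected_components(g_remaining)]
    if not sizes:
        return 0.0
    if sigma == "giant":
        threshold = max(sizes)
        sizes.remove(threshold)  # drop exactly one giant; equal-size peers stay
        return sum(s * s for s in sizes if s < threshold) / n_original
    return sum(s * s for s in sizes if s < sigma) / n_original


def removal_experiment(
    g: nx.Graph,
    ranking: RankingResult,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    sigma_rule: int | str = "giant",
    count_rule: str = "floor",
) -> AttackCurve:
    """Static targeted attack along a removal-fraction grid."""
    if len(fractions) == 0:
        raise ValueError("empty fraction grid")
    fractions = tuple(sorted(fractions))
    if fractions[0] < 0 or fractions[-1] > 1:
        raise ValueError("fractions must lie in [0, 1]")
    if set(ranking.order) != set(g.nodes):
        raise ValueError("ranking does not cover the graph's nodes")
    n = g.number_of_nodes()
    removed, ps, pe, ss = [], [], [], []
    for q in fractions:
        k = removal_count(q, n, count_rule)
        h = g.copy()
        h.remove_nodes_from(ranking.order[:k])
        removed.append(k)
        ps.append(max_connectivity(g, h))
        pe.append(remaining_edges(g, h))
        ss.append(sensitivity(h, n, sigma_rule))
    return AttackCurve(
        ranking.metric_name,
        fractions,
        tuple(removed),
        tuple(ps),
        tuple(pe),
        tuple(ss),
        ranking.order,
        sigma_rule if isinstance(sigma_rule, str) else str(sigma_rule),
        count_rule,
    )


def peak_removal_ratio(curve: AttackCurve) -> float:
    """Smallest grid fraction at which sensitivity attains its maximum."""
    best = max(curve.sensitivity)
    for f, s in zip(curve.fractions, curve.sensitivity):
        if s == best:
            return f
    raise AssertionError("unreachable: curve is non-empty")


def monotonicity(t: ScoreTable) -> MonotonicityResult:
    """m = (r - 1) / (N - 1) * 100% — the ranker's tie-resolving power."""
    n = len(t.values)
    if n < 2:
        raise ValueError("monotonicity requires at least 2 nodes")
    r = len(set(t.values.values()))
    return MonotonicityResult((r - 1) / (n - 1) * 100.0, r, n)
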