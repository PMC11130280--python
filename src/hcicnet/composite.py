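"""Min–max normalization, the HCIC combination, and ranking.

The hierarchical comprehensive importance coefficient multiplies the
min–max-normalized local coefficient CL (from WNCC) with the normalized
global coefficient CG (from HTGC), divided by a node-independent scale:

    HCIC_i = CL_i * CG_i / ( sqrt(sum_j CL_j / (N-1)) * sqrt(sum_j CG_j / (N-1)) )

The denominator is identical for every node (it is kept literal anyway,
for anyone comparing raw values), so the HCIC *ranking* equals the
ranking by the product CL_i * CG_i. Low HCIC = important.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import groupby

import networkx as nx

from .local import wncc
from .scores import LOW, ScoreTable
from .shells import htgc

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankingResult:
    """Total order over nodes, most important first, with tie structure."""

    order: tuple[str, ...]
    tie_groups: tuple[tuple[str, ...], ...]
    metric_name: str
    orientation: str

    @property
    def n_distinct(self) -> int:
        return len(self.tie_groups)

    def top(self, count: int) -> list[str]:
        return list(self.order[:count])


def minmax_normalize(t: ScoreTable) -> ScoreTable:
    """Rescale values to [0, 1]; a constant table maps to all zeros."""
    lo, hi = min(t.values.values()), max(t.values.values())
    if hi == lo:
        log.warning("constant %s table: min-max normalization yields all zeros", t.metric_name)
        vals = {n: 0.0 for n in t.values}
    else:
        vals = {n: (v - lo) / (hi - lo) for n, v in t.values.items()}
    return ScoreTable(f"{t.metric_name}_norm", vals, t.orientation)


def hcic(g: nx.Graph) -> ScoreTable:
    """Composite local+global coefficient for every node (low = important)."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("HCIC requires at least 2 nodes")
    cl = minmax_normalize(wncc(g))
    cg = minmax_normalize(htgc(g))
    denom = math.sqrt(sum(cl.values.values()) / (n - 1)) * math.sqrt(
        sum(cg.values.values()) / (n - 1)
    )
    if denom == 0:
        # both tables constant (e.g. vertex-transitive graph): all products
        # are 0 anyway, keep the table total
        log.warning("degenerate HCIC denominator; returning all-zero table")
        return ScoreTable("hcic", {i: 0.0 for i in g.nodes}, LOW)
    return ScoreTable("hcic", {i: cl[i] * cg[i] / denom for i in g.nodes}, LOW)


def rank_nodes(t: ScoreTable, tie_rule=None) -> RankingResult:
    """Sort nodes most-important-first honoring the table's orientation.

    Ties are broken for the *order* only (default: ascending node label);
    the true tie groups are preserved for the monotonicity indicator.
    """
    tie_rule = tie_rule or (lambda n: n)
    nodes = sorted(t.values, key=tie_rule)
    nodes.sort(key=t.importance_key, reverse=True)
    groups = tuple(
        tuple(grp) for _, grp in groupby(nodes, key=lambda n: t.values[n])
    )
    return RankingResult(tuple(nodes), groups, t.metric_name, t.orientation)
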