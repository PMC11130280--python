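"""Name -> ranker registry shared by the CLI and the attack harness."""

from __future__ import annotations

from typing import Callable

import networkx as nx

from . import baselines, composite, local, shells
from .scores import ScoreTable

RankerFn = Callable[..., ScoreTable]


def _ranker(fn, needs_seed=False, needs_l=False):
    def call(g: nx.Graph, *, seed: int = 0, ci_radius: int = 2) -> ScoreTable:
        if needs_seed:
            return fn(g, seed)
        if needs_l:
            return fn(g, ci_radius)
        return fn(g)

    return call


RANKERS: dict[str, RankerFn] = {
    "dc": _ranker(baselines.degree_centrality),
    "ci": _ranker(baselines.collective_influence, needs_l=True),
    "wl": _ranker(baselines.wl_score),
    "dwt": _ranker(baselines.dwt_score),
    "kshell": _ranker(shells.kshell_table),
    "iks": _ranker(shells.iks),
    "kpd": _ranker(baselines.kpd_score),
    "incc": _ranker(baselines.incc_score),
    "ncc": _ranker(local.ncc_table),
    "wncc": _ranker(local.wncc),
    "htgc": _ranker(shells.htgc),
    "hcic": _ranker(composite.hcic),
    "random": _ranker(baselines.random_score, needs_seed=True),
}


def get_ranker(name: str) -> RankerFn:
    try:
        return RANKERS[name]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; known: {', '.join(sorted(RANKERS))}"
        ) from None
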