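"""Score tables: one ranker's node -> value map plus orientation.

``orientation`` records whether a *low* or *high* value marks an important
node — the constraint-style coefficients (NCC, WNCC, HTGC, HCIC, DWT) are
negatively correlated with importance, the degree-style ones positively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

LOW = "low-is-important"
HIGH = "high-is-important"


@dataclass(frozen=True)
class ScoreTable:
    metric_name: str
    values: Mapping[str, float] = field(repr=False)
    orientation: str = HIGH

    def __post_init__(self):
        if self.orientation not in (LOW, HIGH):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    def importance_key(self, node: str) -> float:
        """Score transformed so that larger always means more important."""
        v = self.values[node]
        return -v if self.orientation == LOW else v

    def to_csv(self, target) -> None:
        own = isinstance(target, str)
        fh = open(target, "w") if own else target
        try:
            fh.write(f"# metric={self.metric_name} orientation={self.orientation}\n")
            fh.write("node,value\n")
            for node in sorted(self.values):
                fh.write(f"{node},{self.values[node]!r}\n")
        finally:
            if own:
                fh.close()
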