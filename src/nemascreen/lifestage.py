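"""COPAS life-stage gating and the life-stage distribution heat map.

Flow events are classified by axis-aligned rectangular gates in the
(time-of-flight, extinction) plane — TOF proxies worm length, extinction
optical density — into L1-L4 and adult; events outside every gate are
counted unclassified. Gates must be pairwise non-overlapping so each event
has at most one home. Distributions over treatments are binned against a
count scale (e.g. >15,000 down to <10 animals) for heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wells import HATCHED_STAGES


@dataclass
class StageGate:
    stage: str
    tof_range: tuple[float, float]
    ec_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.tof_range[0] > self.tof_range[1]:
            raise ValueError(f"gate {self.stage}: TOF min > max")
        if self.ec_range[0] > self.ec_range[1]:
            raise ValueError(f"gate {self.stage}: EC min > max")

    def overlaps(self, other: "StageGate") -> bool:
        t = self.tof_range[0] <= other.tof_range[1] and other.tof_range[0] <= self.tof_range[1]
        e = self.ec_range[0] <= other.ec_range[1] and other.ec_range[0] <= self.ec_range[1]
        return t and e


@dataclass
class StageDistribution:
    treatment: str
    counts: dict[str, int]
    unclassified: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unclassified


def validate_gates(gates: list[StageGate]) -> None:
    """Reject any pair of overlapping rectangles, naming the pair."""
    for i, a in enumerate(gates):
        for b in gates[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"overlapping stage gates: {a.stage} and {b.stage}")


def classify_events(
    events: pd.DataFrame,
    gates: list[StageGate],
    treatment: str = "",
) -> StageDistribution:
    """Assign each event to the unique gate containing its (TOF, EC).

    Returns per-stage counts plus an unclassified count; the partition
    always sums to the number of events.
    """
    validate_gates(gates)
    tof = events["tof"].to_numpy(dtype=float)
    ec = events["ec"].to_numpy(dtype=float)
    counts: dict[str, int] = {s: 0 for s in HATCHED_STAGES}
    assigned = np.zeros(len(events), dtype=bool)
    for g in gates:
        inside = (
            (tof >= g.tof_range[0]) & (tof <= g.tof_range[1])
            & (ec >= g.ec_range[0]) & (ec <= g.ec_range[1])
        )
        counts[g.stage] = counts.get(g.stage, 0) + int(inside.sum())
        assigned |= inside
    return StageDistribution(
        treatment=treatment,
        counts=counts,
        unclassified=int((~assigned).sum()),
    )


def heatmap_matrix(
    dists: list[StageDistribution],
    breakpoints: list[float],
    stages: tuple[str, ...] = HATCHED_STAGES,
) -> pd.DataFrame:
    """Bin each (treatment, stage) count against ``breakpoints``.

    Bin 0 holds counts <= the first breakpoint, the last bin counts above
    the final breakpoint; a count equal to a breakpoint falls in the lower
    bin. Rows keep the input treatment order.
    """
    bp = np.asarray(breakpoints, dtype=float)
    if bp.size == 0:
        raise ValueError("breakpoints must be non-empty")
    if not np.all(np.diff(bp) > 0):
        raise ValueError("breakpoints must be strictly increasing")
    mat = np.empty((len(dists), len(stages)), dtype=int)
    for i, d in enumerate(dists):
        for j, s in enumerate(stages):
            mat[i, j] = int(np.searchsorted(bp, d.counts.get(s, 0), side="left"))
    return pd.DataFrame(mat, index=[d.treatment for d in dists], columns=list(stages))
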