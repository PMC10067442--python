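"""Object gating and per-well aggregation for the laser-scanning cytometer.

Detected fluorescent objects are identified as worms when perimeter, area
and peak intensity all fall inside the published closed ranges
(100-2200 um, 1000-180,000 um^2, 150-1500 AU). Each well is then summarized
by the two screen readouts: total GFP area of gated objects and gated
object count ("number of worms").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .plates import PlateLayout

READOUT_AREA = "gfp_area_total"
READOUT_COUNT = "worm_number"
READOUTS = (READOUT_AREA, READOUT_COUNT)


@dataclass
class GateSpec:
    """Closed intervals on the three per-object features."""

    perimeter_range: tuple[float, float] = (100.0, 2_200.0)
    area_range: tuple[float, float] = (1_000.0, 180_000.0)
    peak_intensity_range: tuple[float, float] = (150.0, 1_500.0)

    def __post_init__(self) -> None:
        for name in ("perimeter_range", "area_range", "peak_intensity_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")


def gate_objects(events: pd.DataFrame, gate: GateSpec | None = None) -> pd.DataFrame:
    """Keep exactly the events with all three features inside their closed
    ranges; row order is preserved."""
    g = gate or GateSpec()
    if len(events) == 0:
        return events.copy()
    mask = (
        events["perimeter"].between(*g.perimeter_range)
        & events["area"].between(*g.area_range)
        & events["peak_intensity"].between(*g.peak_intensity_range)
    )
    return events.loc[mask].copy()


def aggregate_wells(
    gated: pd.DataFrame,
    layout: PlateLayout,
    day: int,
) -> pd.DataFrame:
    """One WellMeasure row per layout well for one read day.

    Wells with no gated events get (0, 0). Events must belong to the
    layout's plate and wells. Columns: plate_id, well, day, gfp_area_total,
    worm_number, role, compound_id, conc_m.
    """
    if len(gated):
        sub = gated.loc[(gated["plate_id"] == layout.plate_id) & (gated["day"] == day)]
        known = set(layout.table["well"])
        unknown = set(sub["well"]) - known
        if unknown:
            raise KeyError(
                f"events reference wells absent from plate {layout.plate_id}: "
                f"{sorted(unknown)[:5]}"
            )
        agg = sub.groupby("well")["area"].agg(["sum", "count"])
    else:
        agg = pd.DataFrame(columns=["sum", "count"])

    out = layout.table[["well", "role", "compound_id", "conc_m"]].copy()
    out.insert(0, "plate_id", layout.plate_id)
    out.insert(2, "day", day)
    out[READOUT_AREA] = out["well"].map(agg["sum"]).fillna(0.0)
    out[READOUT_COUNT] = out["well"].map(agg["count"]).fillna(0).astype(int)
    return out[
        ["plate_id", "well", "day", READOUT_AREA, READOUT_COUNT, "role", "compound_id", "conc_m"]
    ]
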