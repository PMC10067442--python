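"""384-well plate layouts and the inter-plate titration design.

The screen design: every library compound appears once per plate at a
single stock concentration; successive plates carry successive 1:5
dilutions (seven points by default), and the final in-well concentration is
the stock divided by the in-well dilution factor (240-fold by default).
Column 1 of every plate is DMSO vehicle (neutral control); column 2 is the
levamisole toxicity control — eight wells at the fixed full-kill
concentration and eight wells as a 1:3 eight-point titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .wells import N_COLS, N_ROWS, ROW_LETTERS, well_name

ROLE_SAMPLE = "sample"
ROLE_NEUTRAL = "neutral_control"
ROLE_TOXIC = "toxic_control_titration"
ROLE_INTERNAL = "internal_control"
ROLES = (ROLE_SAMPLE, ROLE_NEUTRAL, ROLE_TOXIC, ROLE_INTERNAL)

#: sample wells per plate: columns 3-24 of 16 rows
SAMPLE_CAPACITY = (N_COLS - 2) * N_ROWS

TOXIC_CONTROL_ID = "levamisole"


@dataclass
class PlateLayout:
    """One 384-well plate: a table with one row per well.

    ``table`` columns: well, role, compound_id (empty string for DMSO),
    conc_m (final in-well molar; 0 for neutral controls).
    """

    plate_id: str
    table: pd.DataFrame
    plate_day_read_schedule: list[int] = field(default_factory=lambda: [0, 3, 7])

    def __post_init__(self) -> None:
        if len(self.table) != N_ROWS * N_COLS:
            raise ValueError(
                f"plate {self.plate_id}: expected {N_ROWS * N_COLS} wells, got {len(self.table)}"
            )
        bad = self.table.loc[(self.table.role == ROLE_NEUTRAL) & (self.table.conc_m != 0)]
        if len(bad):
            raise ValueError(f"plate {self.plate_id}: neutral_control wells with nonzero conc")
        if not self.table.role.isin(ROLES).all():
            raise ValueError(f"plate {self.plate_id}: unknown role")

    def sample_wells(self) -> pd.DataFrame:
        return self.table.loc[self.table.role == ROLE_SAMPLE]

    def well_map(self) -> dict[str, tuple[str, str, float]]:
        return {
            r.well: (r.role, r.compound_id, r.conc_m)
            for r in self.table.itertuples(index=False)
        }


def _control_columns(in_well_dilution: float) -> list[dict]:
    """Column-1 DMSO and column-2 levamisole control wells."""
    rows: list[dict] = []
    for r in range(N_ROWS):
        rows.append(
            {"well": well_name(r, 0), "role": ROLE_NEUTRAL, "compound_id": "", "conc_m": 0.0}
        )
    # column 2: rows A-H fixed 10 mM stock (full kill), rows I-P 1:3 titration
    # from 10 mM stock down to 4.57 uM stock
    full_kill_stock = 10e-3
    for r in range(8):
        rows.append(
            {
                "well": well_name(r, 1),
                "role": ROLE_TOXIC,
                "compound_id": TOXIC_CONTROL_ID,
                "conc_m": full_kill_stock / in_well_dilution,
            }
        )
    for k in range(8):
        rows.append(
            {
                "well": well_name(8 + k, 1),
                "role": ROLE_TOXIC,
                "compound_id": TOXIC_CONTROL_ID,
                "conc_m": full_kill_stock / 3**k / in_well_dilution,
            }
        )
    return rows


def make_interplate_titration(
    library,
    n_points: int = 7,
    dilution_factor: float = 5.0,
    top_stock: float = 10e-3,
    in_well_dilution: float = 240.0,
    *,
    plate_prefix: str = "P",
    read_days: tuple[int, ...] = (0, 3, 7),
    allow_split: bool = True,
) -> list[PlateLayout]:
    """Lay out the inter-plate titration: point ``k`` carries every compound
    at stock ``top_stock / dilution_factor**k``, final concentration
    stock / ``in_well_dilution``.

    A library larger than one plate's 352 sample wells is split across as
    many plates per point as needed (ids suffixed ``a``, ``b``, …) when
    ``allow_split``; otherwise a ValueError names the capacity.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    if top_stock <= 0:
        raise ValueError("top_stock must be > 0")
    if in_well_dilution < 1:
        raise ValueError("in_well_dilution must be >= 1")
    n = len(library)
    if n == 0:
        raise ValueError("empty library")
    if n > SAMPLE_CAPACITY and not allow_split:
        raise ValueError(
            f"library of {n} compounds exceeds the {SAMPLE_CAPACITY} sample wells of one plate"
        )

    n_split = -(-n // SAMPLE_CAPACITY)  # ceil
    chunks = [library[i * SAMPLE_CAPACITY:(i + 1) * SAMPLE_CAPACITY] for i in range(n_split)]
    sample_well_order = [well_name(r, c) for c in range(2, N_COLS) for r in range(N_ROWS)]

    layouts: list[PlateLayout] = []
    for k in range(n_points):
        stock = top_stock / dilution_factor**k
        final = stock / in_well_dilution
        for s, chunk in enumerate(chunks):
            suffix = chr(ord("a") + s) if n_split > 1 else ""
            rows = _control_columns(in_well_dilution)
            for w, cpd in zip(sample_well_order, chunk):
                rows.append(
                    {"well": w, "role": ROLE_SAMPLE, "compound_id": cpd.compound_id, "conc_m": final}
                )
            # unfilled sample wells stay DMSO-only vehicle (neutral role, conc 0)
            for w in sample_well_order[len(chunk):]:
                rows.append({"well": w, "role": ROLE_NEUTRAL, "compound_id": "", "conc_m": 0.0})
            table = pd.DataFrame(rows).sort_values("well", kind="stable").reset_index(drop=True)
            layouts.append(
                PlateLayout(
                    plate_id=f"{plate_prefix}{k + 1:02d}{suffix}",
                    table=table,
                    plate_day_read_schedule=list(read_days),
                )
            )
    return layouts


def layouts_to_frame(layouts: list[PlateLayout]) -> pd.DataFrame:
    frames = []
    for lay in layouts:
        t = lay.table.copy()
        t.insert(0, "plate_id", lay.plate_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def layouts_from_frame(frame: pd.DataFrame, read_days: tuple[int, ...] = (0, 3, 7)) -> list[PlateLayout]:
    frame = frame.fillna({"compound_id": ""})
    out = []
    for pid, grp in frame.groupby("plate_id", sort=True):
        out.append(
            PlateLayout(
                plate_id=str(pid),
                table=grp.drop(columns="plate_id").reset_index(drop=True),
                plate_day_read_schedule=list(read_days),
            )
        )
    return out
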