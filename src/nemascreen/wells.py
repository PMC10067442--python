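"""384-well plate geometry and well-name grammar.

Wells are named row letter + zero-padded column, ``A01`` … ``P24``
(16 rows x 24 columns).
"""

from __future__ import annotations

import re

N_ROWS = 16
N_COLS = 24
N_WELLS = N_ROWS * N_COLS

ROW_LETTERS = "ABCDEFGHIJKLMNOP"

WELL_RE = re.compile(r"^([A-P])(0[1-9]|1[0-9]|2[0-4])$")

STAGES = ("egg", "L1", "L2", "L3", "L4", "adult")
#: stages visible to the cytometers (eggs carry too little GFP to gate)
HATCHED_STAGES = STAGES[1:]


def well_name(row: int, col: int) -> str:
    """Name for 0-based (row, col); e.g. (0, 0) -> 'A01'."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"(row={row}, col={col}) outside 16x24 plate")
    return f"{ROW_LETTERS[row]}{col + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    """0-based (row, col) for a well name; raises ValueError on bad grammar."""
    m = WELL_RE.match(name)
    if m is None:
        raise ValueError(f"invalid well name {name!r} (expected A01..P24)")
    return ROW_LETTERS.index(m.group(1)), int(m.group(2)) - 1


def is_valid_well(name: str) -> bool:
    return WELL_RE.match(str(name)) is not None


def all_wells() -> list[str]:
    """All 384 well names in row-major order."""
    return [well_name(r, c) for r in range(N_ROWS) for c in range(N_COLS)]
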