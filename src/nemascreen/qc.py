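"""Plate quality statistics and percent-activity normalization.

From each plate's DMSO (neutral) and full-kill levamisole (positive)
control wells:

    S/B = mu_n / mu_p
    S/N = (mu_n - mu_p) / sqrt(sigma_n^2 + sigma_p^2)
    Z'  = 1 - 3 (sigma_n + sigma_p) / |mu_n - mu_p|

with mu the mean and sigma the sample SD (n-1). Raw well readouts are then
mapped to percent activity on the control scale,

    activity% = 100 (x - mu_n) / (mu_n - mu_p),

so the neutral mean is 0% and the positive mean is -100% (loss of signal).
Statistics are computed per plate, per day, per readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plates import ROLE_NEUTRAL, ROLE_TOXIC


@dataclass
class ControlStats:
    mu_neutral: float
    sigma_neutral: float
    mu_positive: float
    sigma_positive: float
    n_neutral: int
    n_positive: int


@dataclass
class PlateQC:
    plate_id: str
    day: int
    readout: str
    s_b: float
    s_n: float
    z_prime: float


def control_stats(
    wells: pd.DataFrame,
    readout: str,
    positive_conc: float | None = None,
) -> ControlStats:
    """Control means and sample SDs for one plate/day/readout.

    Positive controls are the toxicity-control wells at the single full-kill
    concentration (the maximum toxic-control concentration on the plate
    unless ``positive_conc`` is given); the intra-plate 1:3 titration wells
    are excluded and can instead be fitted as a control curve.
    """
    neutral = wells.loc[wells["role"] == ROLE_NEUTRAL, readout].to_numpy(dtype=float)
    toxic = wells.loc[wells["role"] == ROLE_TOXIC]
    if len(toxic):
        conc = positive_conc if positive_conc is not None else toxic["conc_m"].max()
        pos = toxic.loc[np.isclose(toxic["conc_m"], conc), readout].to_numpy(dtype=float)
    else:
        pos = np.array([])
    plate = wells["plate_id"].iloc[0] if len(wells) else "?"
    if len(neutral) < 2:
        raise ValueError(f"plate {plate}: fewer than 2 neutral_control wells")
    if len(pos) < 2:
        raise ValueError(f"plate {plate}: fewer than 2 full-kill toxic_control_titration wells")
    return ControlStats(
        mu_neutral=float(neutral.mean()),
        sigma_neutral=float(neutral.std(ddof=1)),
        mu_positive=float(pos.mean()),
        sigma_positive=float(pos.std(ddof=1)),
        n_neutral=len(neutral),
        n_positive=len(pos),
    )


def plate_quality(
    stats: ControlStats,
    plate_id: str = "",
    day: int = 0,
    readout: str = "",
    sn_mode: str = "quadrature",
) -> PlateQC:
    """S/B, S/N and Z' from control statistics.

    Undefined statistics (zero denominators) are reported as NaN rather
    than raising — a bad plate should be flagged, not fatal. ``sn_mode``
    'quadrature' divides by sqrt(sigma_n^2 + sigma_p^2); 'neutral' divides
    by sigma_n alone.
    """
    s_b = stats.mu_neutral / stats.mu_positive if stats.mu_positive != 0 else math.nan
    window = stats.mu_neutral - stats.mu_positive
    if sn_mode == "quadrature":
        noise = math.hypot(stats.sigma_neutral, stats.sigma_positive)
    elif sn_mode == "neutral":
        noise = stats.sigma_neutral
    else:
        raise ValueError(f"unknown sn_mode {sn_mode!r}")
    s_n = window / noise if noise != 0 else (math.inf if window > 0 else math.nan)
    if window != 0:
        z = 1.0 - 3.0 * (stats.sigma_neutral + stats.sigma_positive) / abs(window)
    else:
        z = math.nan
    return PlateQC(plate_id=plate_id, day=day, readout=readout, s_b=s_b, s_n=s_n, z_prime=z)


def normalize_wells(
    wells: pd.DataFrame,
    stats: ControlStats,
    readout: str,
) -> pd.DataFrame:
    """Add ``activity_pct`` and ``readout`` columns on the 0 / -100 control
    scale. A plate whose control means coincide is unnormalizable: every
    well gets NaN activity and ``normalizable`` False."""
    out = wells.copy()
    out["readout"] = readout
    window = stats.mu_neutral - stats.mu_positive
    if window == 0:
        out["activity_pct"] = np.nan
        out["normalizable"] = False
    else:
        out["activity_pct"] = 100.0 * (out[readout].astype(float) - stats.mu_neutral) / window
        out["normalizable"] = True
    return out
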