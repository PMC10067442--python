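"""Titration assembly and four-parameter logistic (Hill) fitting.

Normalized percent-activity wells are assembled into one concentration
series per (compound, readout, day) and fitted with the variable-slope
four-parameter logistic on log10 concentration:

    y(x) = bottom + (top - bottom) / (1 + 10^((log10 EC50 - x) * h)),

x = log10 c. With h < 0 the curve falls from ``top`` (low concentration)
to ``bottom`` (high concentration) — the loss-of-signal geometry of a
viability screen normalized to 0 / -100%. Fitting is deterministic
weighted least squares with box constraints and a small multi-start over
slope initializations; series with fewer than four points fall back to a
three-parameter fit with the bottom fixed at full kill (-100%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .plates import ROLE_SAMPLE


@dataclass
class TitrationSeries:
    compound_id: str
    readout: str
    day: int
    conc: np.ndarray          # molar, strictly increasing
    activity: np.ndarray      # percent
    n: np.ndarray             # replicate wells averaged into each point
    plate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.n = np.asarray(self.n, dtype=int) if len(np.atleast_1d(self.n)) else np.ones_like(self.conc, dtype=int)
        if len(self.conc) < 2:
            raise ValueError(f"{self.compound_id}: a titration needs >= 2 points")
        if not np.all(np.diff(self.conc) > 0):
            raise ValueError(f"{self.compound_id}: concentrations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.conc)


@dataclass
class HillFit:
    bottom: float
    top: float
    log_ec50: float
    hill_slope: float
    r2: float
    converged: bool
    masked_points: tuple[int, ...] = ()
    extrapolated: bool = False
    n_points: int = 0

    @property
    def ec50(self) -> float:
        return float(10.0 ** self.log_ec50)


@dataclass
class FitConstraints:
    """Box constraints and fallback behaviour for the 4PL fit."""

    bottom_bounds: tuple[float, float] = (-120.0, 20.0)
    top_bounds: tuple[float, float] = (-20.0, 120.0)
    slope_magnitude_bounds: tuple[float, float] = (0.1, 15.0)
    log_ec50_pad: float = 2.0        # decades beyond the tested range
    fixed_bottom: float | None = None
    fallback_bottom: float = -100.0  # used when < 4 points force a 3-parameter fit
    degenerate_span: float = 20.0    # % span below which a single start is used


def hill_curve(logc, bottom, top, log_ec50, hill_slope):
    """Variable-slope 4PL evaluated at log10 concentration."""
    t = np.clip((log_ec50 - np.asarray(logc, dtype=float)) * hill_slope, -50.0, 50.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** t)


def _hill_jacobian(logc, bottom, top, log_ec50, hill_slope):
    """Analytic partials of the 4PL wrt (bottom, top, log_ec50, hill_slope)."""
    x = np.asarray(logc, dtype=float)
    u = 10.0 ** np.clip((log_ec50 - x) * hill_slope, -50.0, 50.0)
    denom = 1.0 + u
    g = (top - bottom) * np.log(10.0) * u / denom**2
    return np.column_stack([
        1.0 - 1.0 / denom,
        1.0 / denom,
        -g * hill_slope,
        -g * (log_ec50 - x),
    ])


def assemble_series(
    normalized: pd.DataFrame,
    min_points: int = 2,
) -> list[TitrationSeries]:
    """Group normalized sample wells into per-(compound, readout, day)
    series; duplicate concentrations are averaged with their replicate
    count recorded. Compounds with fewer than ``min_points`` distinct
    concentrations are excluded with a warning."""
    samples = normalized.loc[
        (normalized["role"] == ROLE_SAMPLE) & normalized["activity_pct"].notna()
    ]
    out: list[TitrationSeries] = []
    for (cpd, readout, day), grp in samples.groupby(
        ["compound_id", "readout", "day"], sort=True
    ):
        agg = (
            grp.groupby("conc_m")
            .agg(activity=("activity_pct", "mean"), n=("activity_pct", "size"))
            .sort_index()
        )
        if len(agg) < min_points:
            warnings.warn(
                f"{cpd} ({readout}, day {day}): only {len(agg)} distinct "
                f"concentration(s); excluded from fitting",
                stacklevel=2,
            )
            continue
        out.append(
            TitrationSeries(
                compound_id=str(cpd),
                readout=str(readout),
                day=int(day),
                conc=agg.index.to_numpy(),
                activity=agg["activity"].to_numpy(),
                n=agg["n"].to_numpy(),
                plate_ids=sorted(grp["plate_id"].unique().tolist()),
            )
        )
    return out


def _initial_guesses(logc, y, constraints: FitConstraints):
    """Deterministic starts: asymptotes from extreme-concentration medians,
    log EC50 from the half-effect crossing, three slope magnitudes."""
    k = max(1, len(y) // 3)
    low = float(np.median(y[:k]))
    high = float(np.median(y[-k:]))
    direction = -1.0 if high < low else 1.0   # falling response -> negative slope
    top0 = max(low, high)
    bot0 = min(low, high)
    mid = (low + high) / 2.0
    idx = int(np.argmin(np.abs(y - mid)))
    le0 = float(logc[idx])
    starts = []
    for mag in (1.0, 3.0, 0.3):
        starts.append((bot0, top0, le0, direction * mag))
    return starts


def fit_hill(
    series: TitrationSeries,
    constraints: FitConstraints | None = None,
    mask: tuple[int, ...] = (),
) -> HillFit:
    """Deterministic constrained least-squares 4PL fit.

    Points in ``mask`` are excluded; the loss weights each point by its
    replicate count. Non-convergence is reported in the ``converged`` flag,
    never raised. The EC50 is flagged ``extrapolated`` when it falls
    outside the tested concentration range.
    """
    con = constraints or FitConstraints()
    keep = np.setdiff1d(np.arange(len(series)), np.asarray(mask, dtype=int))
    logc = np.log10(series.conc[keep])
    y = series.activity[keep]
    w = series.n[keep].astype(float)

    le_lo, le_hi = logc.min() - con.log_ec50_pad, logc.max() + con.log_ec50_pad
    fix_bottom = con.fixed_bottom
    if fix_bottom is None and len(y) < 4:
        fix_bottom = con.fallback_bottom
    starts = _initial_guesses(logc, y, con)
    sqw = np.sqrt(w)
    # a clearly sub-threshold series has no slope structure worth a
    # multi-start search; one bounded start suffices
    degenerate = float(np.ptp(y)) < con.degenerate_span
    if degenerate:
        starts = starts[:1]
    max_nfev = 60 if degenerate else 150

    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    best = None
    for bot0, top0, le0, h0 in starts:
        if fix_bottom is None:
            p0 = np.array([
                np.clip(bot0, *con.bottom_bounds),
                np.clip(top0, *con.top_bounds),
                np.clip(le0, le_lo, le_hi),
                h0,
            ])
            lo = [con.bottom_bounds[0], con.top_bounds[0], le_lo, -con.slope_magnitude_bounds[1]]
            hi = [con.bottom_bounds[1], con.top_bounds[1], le_hi, con.slope_magnitude_bounds[1]]

            def fun(p):
                return (hill_curve(logc, *p) - y) * sqw

            def jac(p):
                return _hill_jacobian(logc, *p) * sqw[:, None]
        else:
            fb = fix_bottom
            p0 = np.array([np.clip(top0, *con.top_bounds), np.clip(le0, le_lo, le_hi), h0])
            lo = [con.top_bounds[0], le_lo, -con.slope_magnitude_bounds[1]]
            hi = [con.top_bounds[1], le_hi, con.slope_magnitude_bounds[1]]

            def fun(p):
                return (hill_curve(logc, fb, *p) - y) * sqw

            def jac(p):
                return _hill_jacobian(logc, fb, *p)[:, 1:] * sqw[:, None]
        try:
            res = least_squares(fun, p0, jac=jac, bounds=(lo, hi),
                                max_nfev=max_nfev, method="trf")
        except ValueError:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        params = tuple(res.x) if fix_bottom is None else (fix_bottom, *res.x)
        sse = 2.0 * float(res.cost)
        if best is None or sse < best[0]:
            best = (sse, params)
        if ss_tot > 0 and sse < 0.05 * ss_tot:
            break  # essentially perfect; further starts cannot help

    if best is None:
        return HillFit(
            bottom=np.nan, top=np.nan, log_ec50=np.nan, hill_slope=np.nan,
            r2=np.nan, converged=False, masked_points=tuple(mask), n_points=len(y),
        )
    _, (bottom, top, log_ec50, slope) = best
    yhat = hill_curve(logc, bottom, top, log_ec50, slope)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else np.nan)
    return HillFit(
        bottom=float(bottom),
        top=float(top),
        log_ec50=float(log_ec50),
        hill_slope=float(slope),
        r2=r2,
        converged=True,
        masked_points=tuple(sorted(int(i) for i in mask)),
        extrapolated=not (logc.min() <= log_ec50 <= logc.max()),
        n_points=len(y),
    )


def mask_outliers(
    series: TitrationSeries,
    fit: HillFit,
    threshold: float = 3.0,
    constraints: FitConstraints | None = None,
    max_masked: int = 2,
) -> HillFit:
    """Iteratively mask the single worst point whose |residual| exceeds
    ``threshold`` robust residual SDs, refit, and stop at convergence or the
    mask cap (2 points on a 7-point series).

    The residual scale is 1.4826 x MAD rather than the RMS: a single gross
    outlier inflates the RMS enough to hide itself, while the median
    absolute deviation stays anchored to the well-fitted points.
    """
    current = fit
    masked = list(fit.masked_points)
    while len(masked) < max_masked and current.converged:
        keep = np.setdiff1d(np.arange(len(series)), np.asarray(masked, dtype=int))
        if len(keep) <= 4:
            break
        logc = np.log10(series.conc[keep])
        resid = series.activity[keep] - hill_curve(
            logc, current.bottom, current.top, current.log_ec50, current.hill_slope
        )
        s = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        if s == 0:
            break
        worst = int(np.argmax(np.abs(resid)))
        if abs(resid[worst]) / s <= threshold:
            break
        masked.append(int(keep[worst]))
        current = fit_hill(series, constraints, mask=tuple(masked))
    return replace(current, masked_points=tuple(sorted(masked)))


def fits_to_frame(series_list: list[TitrationSeries], fits: list[HillFit]) -> pd.DataFrame:
    rows = []
    for s, f in zip(series_list, fits):
        rows.append(
            {
                "compound_id": s.compound_id,
                "readout": s.readout,
                "day": s.day,
                "bottom": f.bottom,
                "top": f.top,
                "log_ec50": f.log_ec50,
                "ec50_m": f.ec50 if np.isfinite(f.log_ec50) else np.nan,
                "hill_slope": f.hill_slope,
                "r2": f.r2,
                "converged": f.converged,
                "extrapolated": f.extrapolated,
                "n_masked": len(f.masked_points),
            }
        )
    return pd.DataFrame(rows)
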