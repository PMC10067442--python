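"""qHTS curve classification and follow-up prioritization.

Each fitted concentration-response curve receives an ordinal curve class
(CC): class 1 when both asymptotes are supported by tested points, class 2
when only one is, class 3 for low-confidence activity (poor fit, or
response confined to the highest tested concentration), class 4 for
inactive. Sub-class .1 marks high efficacy (>= 80% by default), .2 partial
efficacy. The sign carries the response direction; in a loss-of-signal
viability screen active calls are the negative classes
{-1.1, -1.2, -2.1, -2.2, -3}.

Follow-up prioritization ranks compounds by day-3 and day-7 class quality
and then prefers compounds inactive in the human-cell counter screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doseresponse import HillFit, TitrationSeries, hill_curve

ACTIVE_LOSS_CLASSES = (-1.1, -1.2, -2.1, -2.2, -3.0)
ACTIVE_GAIN_CLASSES = (1.1, 1.2, 2.1, 2.2, 3.0)
HIGH_QUALITY_LOSS = (-1.1, -1.2, -2.1)
MODERATE_LOSS = (-2.2, -3.0)


@dataclass
class ClassThresholds:
    """All classification knobs in one block.

    ``min_efficacy`` is the activity floor, taken as
    max(min_efficacy_floor, 3 * neutral_sd) when the neutral-control
    activity SD is known; ``plateau_tol_frac`` is the fraction of the
    fitted span within which a point counts as supporting an asymptote.
    """

    high_efficacy: float = 80.0
    min_efficacy_floor: float = 30.0
    neutral_sd: float | None = None
    r2_floor: float = 0.9
    plateau_tol_frac: float = 0.15
    direction: str = "loss"  # 'loss' (viability screens) or 'gain'

    @property
    def min_efficacy(self) -> float:
        if self.neutral_sd is None:
            return self.min_efficacy_floor
        return max(self.min_efficacy_floor, 3.0 * self.neutral_sd)


@dataclass
class CurveClass:
    compound_id: str
    readout: str
    day: int
    cc: float                  # one of +/-1.1, +/-1.2, +/-2.1, +/-2.2, +/-3, 4
    efficacy: float            # percent response span realized in the tested range
    is_active: bool
    reason: str = ""


@dataclass
class PriorityCall:
    compound_id: str
    tier: int
    day3_cc: float
    day7_cc: float
    counter_cc: float


def _realized_span(fit: HillFit, series: TitrationSeries) -> tuple[float, float]:
    """(signed response change, |span|) of the fitted curve over the tested
    concentration range; the 4PL is monotone so the extremes suffice."""
    lo = float(hill_curve(np.log10(series.conc[0]), fit.bottom, fit.top, fit.log_ec50, fit.hill_slope))
    hi = float(hill_curve(np.log10(series.conc[-1]), fit.bottom, fit.top, fit.log_ec50, fit.hill_slope))
    return hi - lo, abs(hi - lo)


def classify_curve(
    fit: HillFit,
    series: TitrationSeries,
    thresholds: ClassThresholds | None = None,
) -> CurveClass:
    """Assign the qHTS curve class for one fitted series."""
    th = thresholds or ClassThresholds()
    min_eff = th.min_efficacy
    base = dict(compound_id=series.compound_id, readout=series.readout, day=series.day)
    keep = np.setdiff1d(np.arange(len(series)), np.asarray(fit.masked_points, dtype=int))
    act = series.activity[keep]

    if not fit.converged or not np.isfinite(fit.log_ec50):
        # no usable fit: call class 3 if the top concentration alone shows
        # clear activity, else inactive
        top_resp = abs(float(act[-1]))
        rest = np.abs(act[:-1]) if len(act) > 1 else np.array([0.0])
        if top_resp >= min_eff and np.all(rest < min_eff):
            sign = -1.0 if (len(act) and act[-1] < 0) else 1.0
            return CurveClass(**base, cc=sign * 3.0, efficacy=top_resp,
                              is_active=sign < 0 if th.direction == "loss" else sign > 0,
                              reason="no fit; single-concentration activity")
        return CurveClass(**base, cc=4.0, efficacy=0.0, is_active=False, reason="no fit")

    change, span = _realized_span(fit, series)
    sign = -1.0 if change < 0 else 1.0
    active_sign = (sign < 0) if th.direction == "loss" else (sign > 0)

    if span < min_eff:
        return CurveClass(**base, cc=4.0, efficacy=span, is_active=False,
                          reason=f"efficacy {span:.1f}% below floor {min_eff:.1f}%")

    # asymptote support: an unmasked tested point within tolerance of each plateau
    tol = th.plateau_tol_frac * span
    top_plateau = max(fit.top, fit.bottom) if change < 0 else min(fit.top, fit.bottom)
    # plateau approached at low concentration vs high concentration
    low_plateau = float(hill_curve(fit.log_ec50 - 6 / max(abs(fit.hill_slope), 1e-6),
                                   fit.bottom, fit.top, fit.log_ec50, fit.hill_slope))
    high_plateau = float(hill_curve(fit.log_ec50 + 6 / max(abs(fit.hill_slope), 1e-6),
                                    fit.bottom, fit.top, fit.log_ec50, fit.hill_slope))
    support_low = bool(np.any(np.abs(act - low_plateau) <= tol))
    support_high = bool(np.any(np.abs(act - high_plateau) <= tol))
    n_support = int(support_low) + int(support_high)

    # response confined to the top tested concentration
    rest = np.abs(act[:-1] - act[0]) if len(act) > 1 else np.array([0.0])
    confined = abs(act[-1] - act[0]) >= min_eff and np.all(rest < min_eff / 2.0)

    good_fit = np.isfinite(fit.r2) and fit.r2 >= th.r2_floor
    if good_fit and n_support == 2 and not confined:
        cls = 1.0
    elif good_fit and n_support == 1 and not confined:
        cls = 2.0
    else:
        cls = 3.0

    if cls in (1.0, 2.0):
        sub = 0.1 if span >= th.high_efficacy else 0.2
        cc = sign * (cls + sub)
    else:
        cc = sign * 3.0
    return CurveClass(**base, cc=float(np.round(cc, 1)), efficacy=span,
                      is_active=active_sign, reason="")


def is_active_cc(cc: float, direction: str = "loss") -> bool:
    actives = ACTIVE_LOSS_CLASSES if direction == "loss" else ACTIVE_GAIN_CLASSES
    return any(np.isclose(cc, a) for a in actives)


def prioritize(
    calls_day3: dict[str, CurveClass],
    calls_day7: dict[str, CurveClass],
    counter_calls: dict[str, CurveClass] | None = None,
) -> list[PriorityCall]:
    """Deterministic follow-up ranking.

    Tier 1: high-quality active class on day 3 and active on day 7;
    tier 2: moderate day-3 activity (-2.2/-3) with day-7 activity;
    tier 3: day-7 activity only; tier 4: inactive. Within a tier,
    counter-screen-inactive compounds (class 4, no human-cell toxicity)
    rank first; ties break on compound_id.
    """
    counter_calls = counter_calls or {}
    compounds = sorted(set(calls_day3) | set(calls_day7))
    out = []
    for cpd in compounds:
        d3 = calls_day3.get(cpd)
        d7 = calls_day7.get(cpd)
        cc3 = d3.cc if d3 else 4.0
        cc7 = d7.cc if d7 else 4.0
        ctr = counter_calls.get(cpd)
        ccc = ctr.cc if ctr else 4.0
        day7_active = d7.is_active if d7 else False
        if day7_active and any(np.isclose(cc3, c) for c in HIGH_QUALITY_LOSS):
            tier = 1
        elif day7_active and any(np.isclose(cc3, c) for c in MODERATE_LOSS):
            tier = 2
        elif day7_active:
            tier = 3
        else:
            tier = 4
        out.append(PriorityCall(compound_id=cpd, tier=tier, day3_cc=cc3,
                                day7_cc=cc7, counter_cc=ccc))
    # counter class 4 (non-toxic) sorts before toxic within a tier
    out.sort(key=lambda p: (p.tier, 0 if np.isclose(p.counter_cc, 4.0) else 1, p.compound_id))
    return out
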