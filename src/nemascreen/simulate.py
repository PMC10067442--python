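"""Stage-structured worm population dynamics and synthetic cytometer events.

The population model is a discrete daily-time-step Markov chain per well:
eggs hatch to L1 after one day; each hatched worm advances 1 + Bernoulli(1/3)
stages per day (so L1 -> adult averages three days, one life cycle); adults
lay a Poisson brood each day subject to a per-well carrying capacity.
Compound effect is a per-worm per-day kill hazard

    p_kill = efficacy * stage_susceptibility * c^h / (c^h + EC50^h)

evaluated at the well's final concentration. All randomness flows from one
seed; each well gets an independent substream derived by stable hashing of
(plate_id, well), so a well's trajectory does not depend on what else is on
the plate.

Event emission draws one log-normal (area, perimeter, peak intensity)
triple per living hatched worm for the laser-scanning cytometer, plus
Poisson debris objects that fall below the published gate, and one
(TOF, EC, green) triple per worm for the COPAS large-particle sorter with
stage-separated clouds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import CompoundSpec
from .plates import PlateLayout
from .wells import HATCHED_STAGES, STAGES

_STAGE_IDX = {s: i for i, s in enumerate(STAGES)}


def _well_rng(seed: int, plate_id: str, well: str) -> np.random.Generator:
    """Per-well substream: SeedSequence(seed, crc32(plate:well))."""
    tag = zlib.crc32(f"{plate_id}:{well}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


@dataclass
class DynamicsConfig:
    """Population-model parameters.

    Defaults emulate the primary screen: ten synchronized L1 per 30 ul well,
    a three-day L1->adult cycle, food-limited brood, and a 20,000-worm
    carrying capacity (the ceiling of the life-stage heat-map scale).
    """

    seed_count: int = 10
    seed_stage: str = "L1"
    mixed_seeding: bool = False  # split seed_count evenly over hatched stages
    brood_per_adult_per_day: float = 20.0
    carrying_capacity: int = 20_000
    advance_extra_prob: float = 1.0 / 3.0  # P(advance 2 stages in a day)

    def initial_counts(self) -> np.ndarray:
        counts = np.zeros(len(STAGES), dtype=np.int64)
        if self.mixed_seeding:
            per = self.seed_count // len(HATCHED_STAGES)
            rem = self.seed_count - per * len(HATCHED_STAGES)
            for i, s in enumerate(HATCHED_STAGES):
                counts[_STAGE_IDX[s]] = per + (1 if i < rem else 0)
        else:
            counts[_STAGE_IDX[self.seed_stage]] = self.seed_count
        return counts


def hill_hazard(conc: float, ec50: float, hill: float) -> float:
    """Fractional occupancy c^h / (c^h + EC50^h); 0 at zero concentration."""
    if conc <= 0:
        return 0.0
    # compute in log space to dodge overflow at steep slopes
    t = hill * (np.log(conc) - np.log(ec50))
    return float(1.0 / (1.0 + np.exp(-t)))


def kill_probabilities(cpd: CompoundSpec | None, conc: float) -> np.ndarray:
    """Per-stage daily kill probability vector for one well."""
    p = np.zeros(len(STAGES))
    if cpd is None or conc <= 0 or cpd.true_efficacy == 0:
        return p
    occ = hill_hazard(conc, cpd.true_ec50, cpd.true_hill)
    for s, i in _STAGE_IDX.items():
        susc = cpd.stage_susceptibility.get(s, 1.0)
        p[i] = min(1.0, cpd.true_efficacy * susc * occ)
    return p


def _round_stochastic(x: float, rng: np.random.Generator) -> int:
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def _step_day(counts: np.ndarray, p_kill: np.ndarray, cfg: DynamicsConfig,
              rng: np.random.Generator) -> np.ndarray:
    """One day: kill, hatch/advance, lay.

    Advancement splits each cohort proportionally (with stochastic rounding)
    rather than per-worm Bernoulli draws: real larval development is
    synchronized to within hours, so cohort-level splitting keeps the mean
    dwell times without the artificial day-scale timing dispersion a
    per-worm draw would add.
    """
    survivors = rng.binomial(counts, 1.0 - p_kill)
    nxt = np.zeros_like(counts)
    # eggs laid yesterday hatch today
    nxt[_STAGE_IDX["L1"]] += survivors[_STAGE_IDX["egg"]]
    # larvae advance 1 or 2 stages; adults stay adults
    for s in ("L1", "L2", "L3", "L4"):
        i = _STAGE_IDX[s]
        n = survivors[i]
        if n == 0:
            continue
        two = _round_stochastic(n * cfg.advance_extra_prob, rng)
        nxt[min(i + 2, _STAGE_IDX["adult"])] += two
        nxt[i + 1] += n - two
    nxt[_STAGE_IDX["adult"]] += survivors[_STAGE_IDX["adult"]]
    # brood, capped by carrying capacity
    adults = nxt[_STAGE_IDX["adult"]]
    if adults > 0 and cfg.brood_per_adult_per_day > 0:
        room = max(0, cfg.carrying_capacity - int(nxt.sum()))
        eggs = min(int(rng.poisson(adults * cfg.brood_per_adult_per_day)), room)
        nxt[_STAGE_IDX["egg"]] = eggs
    return nxt


def simulate_population(
    layout: PlateLayout,
    library: list[CompoundSpec],
    days: int,
    params: DynamicsConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate every well of ``layout`` for ``days`` days.

    Returns a long table with one row per (well, day 0..days) and integer
    columns egg, L1, L2, L3, L4, adult. The toxicity-control compound
    (present in the layout but not the library) uses levamisole-like
    pharmacology: EC50 5 uM final, Hill 1.5, efficacy 1.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    cfg = params or DynamicsConfig()
    by_id = {c.compound_id: c for c in library}
    control = CompoundSpec(
        compound_id="levamisole",
        annotation="toxicity control",
        true_ec50=5e-6,
        true_hill=1.5,
        true_efficacy=1.0,
        stage_susceptibility={s: 1.0 for s in STAGES},
    )
    records = []
    for row in layout.table.itertuples(index=False):
        cpd = None
        if row.compound_id:
            cpd = by_id.get(row.compound_id)
            if cpd is None and row.compound_id == control.compound_id:
                cpd = control
            if cpd is None:
                raise KeyError(
                    f"layout {layout.plate_id} well {row.well}: unknown compound_id {row.compound_id!r}"
                )
        p_kill = kill_probabilities(cpd, row.conc_m)
        rng = _well_rng(seed, layout.plate_id, row.well)
        counts = cfg.initial_counts()
        records.append((layout.plate_id, row.well, 0, *counts))
        for day in range(1, days + 1):
            counts = _step_day(counts, p_kill, cfg, rng)
            records.append((layout.plate_id, row.well, day, *counts))
    return pd.DataFrame.from_records(
        records, columns=["plate_id", "well", "day", *STAGES]
    )


# ---------------------------------------------------------------------------
# LSC event emission

@dataclass
class OpticsConfig:
    """Per-stage log-normal feature distributions for the laser-scanning
    cytometer, plus a sub-gate debris model.

    Means sit inside the published gate (perimeter 100-2200 um, area
    1000-180,000 um^2, peak 150-1500 AU) and increase monotonically with
    stage; debris means sit below every lower gate bound.
    """

    area_mean: dict[str, float] = field(default_factory=lambda: {
        "L1": 2_000.0, "L2": 5_000.0, "L3": 12_000.0, "L4": 30_000.0, "adult": 70_000.0})
    area_cv: float = 0.25
    perimeter_mean: dict[str, float] = field(default_factory=lambda: {
        "L1": 250.0, "L2": 400.0, "L3": 650.0, "L4": 950.0, "adult": 1_300.0})
    perimeter_cv: float = 0.15
    peak_mean: dict[str, float] = field(default_factory=lambda: {
        "L1": 300.0, "L2": 350.0, "L3": 400.0, "L4": 500.0, "adult": 600.0})
    peak_cv: float = 0.20
    debris_rate: float = 5.0  # Poisson mean objects per well per read
    debris_area_mean: float = 200.0
    debris_perimeter_mean: float = 60.0
    debris_peak_mean: float = 80.0
    debris_cv: float = 0.5


def _lognormal(rng: np.random.Generator, mean: np.ndarray | float, cv: float, size: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def emit_lsc_events(
    states: pd.DataFrame,
    optics: OpticsConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One ObjectEvent per living hatched worm plus Poisson debris objects.

    ``states`` is the simulate_population table (filter it to the read days
    first). Eggs emit nothing. Columns of the result: plate_id, well, day,
    perimeter, area, peak_intensity.
    """
    opt = optics or OpticsConfig()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    states = states.sort_values(["plate_id", "well", "day"], kind="stable")

    plate_parts, well_parts, day_parts = [], [], []
    per_parts, area_parts, peak_parts = [], [], []
    for stage in HATCHED_STAGES:
        n = states[stage].to_numpy(dtype=np.int64)
        total = int(n.sum())
        if total == 0:
            continue
        plate_parts.append(np.repeat(states["plate_id"].to_numpy(), n))
        well_parts.append(np.repeat(states["well"].to_numpy(), n))
        day_parts.append(np.repeat(states["day"].to_numpy(), n))
        area_parts.append(_lognormal(rng, opt.area_mean[stage], opt.area_cv, total))
        per_parts.append(_lognormal(rng, opt.perimeter_mean[stage], opt.perimeter_cv, total))
        peak_parts.append(_lognormal(rng, opt.peak_mean[stage], opt.peak_cv, total))
    # debris
    if opt.debris_rate > 0 and len(states):
        d = rng.poisson(opt.debris_rate, size=len(states))
        total = int(d.sum())
        if total:
            plate_parts.append(np.repeat(states["plate_id"].to_numpy(), d))
            well_parts.append(np.repeat(states["well"].to_numpy(), d))
            day_parts.append(np.repeat(states["day"].to_numpy(), d))
            area_parts.append(_lognormal(rng, opt.debris_area_mean, opt.debris_cv, total))
            per_parts.append(_lognormal(rng, opt.debris_perimeter_mean, opt.debris_cv, total))
            peak_parts.append(_lognormal(rng, opt.debris_peak_mean, opt.debris_cv, total))

    if not plate_parts:
        return pd.DataFrame(
            columns=["plate_id", "well", "day", "perimeter", "area", "peak_intensity"]
        )
    return pd.DataFrame(
        {
            "plate_id": np.concatenate(plate_parts),
            "well": np.concatenate(well_parts),
            "day": np.concatenate(day_parts).astype(int),
            "perimeter": np.concatenate(per_parts),
            "area": np.concatenate(area_parts),
            "peak_intensity": np.concatenate(peak_parts),
        }
    )


# ---------------------------------------------------------------------------
# COPAS event emission

@dataclass
class FlowConfig:
    """Per-stage bivariate log-normal (TOF, EC) clouds for the large-particle
    sorter. Stage means are spaced geometrically (factor 2) so default gates
    of +/-35% around each mean are pairwise disjoint."""

    tof_mean: dict[str, float] = field(default_factory=lambda: {
        "L1": 50.0, "L2": 100.0, "L3": 200.0, "L4": 400.0, "adult": 800.0})
    ec_mean: dict[str, float] = field(default_factory=lambda: {
        "L1": 20.0, "L2": 40.0, "L3": 80.0, "L4": 160.0, "adult": 320.0})
    cv: float = 0.10
    tof_ec_corr: float = 0.5
    green_mean: dict[str, float] = field(default_factory=lambda: {
        "L1": 100.0, "L2": 200.0, "L3": 400.0, "L4": 800.0, "adult": 1_600.0})
    green_cv: float = 0.3
    debris_rate: float = 0.0
    debris_tof_mean: float = 10.0
    debris_ec_mean: float = 4.0

    def default_gates(self, margin: float = 1.35):
        """Axis-aligned stage gates matched to the cloud geometry."""
        from .lifestage import StageGate

        return [
            StageGate(
                stage=s,
                tof_range=(self.tof_mean[s] / margin, self.tof_mean[s] * margin),
                ec_range=(self.ec_mean[s] / margin, self.ec_mean[s] * margin),
            )
            for s in HATCHED_STAGES
        ]


def emit_copas_events(
    states: pd.DataFrame,
    flow: FlowConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One FlowEvent per living hatched worm (plus optional debris).

    Result columns: source_well (plate:well), day, stage (ground truth,
    for recovery tests), tof, ec, green.
    """
    cfg = flow or FlowConfig()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    sigma = np.sqrt(np.log1p(cfg.cv**2))
    cov = sigma**2 * np.array([[1.0, cfg.tof_ec_corr], [cfg.tof_ec_corr, 1.0]])
    states = states.sort_values(["plate_id", "well", "day"], kind="stable")
    src = (states["plate_id"].astype(str) + ":" + states["well"].astype(str)).to_numpy()

    rows = {k: [] for k in ("source_well", "day", "stage", "tof", "ec", "green")}
    for stage in HATCHED_STAGES:
        n = states[stage].to_numpy(dtype=np.int64)
        total = int(n.sum())
        if total == 0:
            continue
        mu = np.log([cfg.tof_mean[stage], cfg.ec_mean[stage]]) - sigma**2 / 2.0
        z = np.exp(rng.multivariate_normal(mu, cov, size=total))
        rows["source_well"].append(np.repeat(src, n))
        rows["day"].append(np.repeat(states["day"].to_numpy(), n))
        rows["stage"].append(np.full(total, stage))
        rows["tof"].append(z[:, 0])
        rows["ec"].append(z[:, 1])
        rows["green"].append(_lognormal(rng, cfg.green_mean[stage], cfg.green_cv, total))
    if cfg.debris_rate > 0 and len(states):
        d = rng.poisson(cfg.debris_rate, size=len(states))
        total = int(d.sum())
        if total:
            rows["source_well"].append(np.repeat(src, d))
            rows["day"].append(np.repeat(states["day"].to_numpy(), d))
            rows["stage"].append(np.full(total, "debris"))
            rows["tof"].append(_lognormal(rng, cfg.debris_tof_mean, 0.5, total))
            rows["ec"].append(_lognormal(rng, cfg.debris_ec_mean, 0.5, total))
            rows["green"].append(_lognormal(rng, 10.0, 0.5, total))

    if not rows["tof"]:
        return pd.DataFrame(columns=["source_well", "day", "stage", "tof", "ec", "green"])
    return pd.DataFrame(
        {
            "source_well": np.concatenate(rows["source_well"]),
            "day": np.concatenate(rows["day"]).astype(int),
            "stage": np.concatenate(rows["stage"]),
            "tof": np.concatenate(rows["tof"]),
            "ec": np.concatenate(rows["ec"]),
            "green": np.concatenate(rows["green"]),
        }
    )
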