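"""End-to-end screen orchestration: simulate -> gate -> QC -> fit ->
classify -> enrich, with one config, one seed, and a reproducible manifest.

Every stage writes its CSV under the configured output directory; the run
manifest records the seed, package version and per-stage row counts, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassThresholds, classify_curve, prioritize
from .config import RunConfig
from .doseresponse import FitConstraints, assemble_series, fit_hill, fits_to_frame, mask_outliers
from .gating import READOUT_AREA, READOUT_COUNT, GateSpec, aggregate_wells, gate_objects
from .library import fingerprint_matrix, library_to_frame, make_library
from .plates import ROLE_NEUTRAL, layouts_to_frame, make_interplate_titration
from .qc import control_stats, normalize_wells, plate_quality
from .simulate import DynamicsConfig, OpticsConfig, emit_lsc_events, simulate_population
from .som import cluster_enrichment, enrichment_heatmap, train_som

log = logging.getLogger("nemascreen")


def _stage(name: str, t0: float, **counts) -> dict:
    # timing goes to the log only: the manifest must be byte-identical
    # across reruns of the same config
    log.info("%s (%.2fs): %s", name, time.perf_counter() - t0, counts)
    return {"stage": name, **counts}


def run_screen(config: RunConfig, write_events: bool = True) -> dict:
    """Execute the full pipeline and return the run manifest.

    ``write_events`` can be disabled for large simulated screens where the
    raw event table is only an intermediate.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "nemascreen", "version": __version__,
                      "seed": config.seed, "stages": []}

    t0 = time.perf_counter()
    library = make_library(seed=config.seed, **config.library)
    library_to_frame(library).to_csv(out / "library.csv", index=False)
    manifest["stages"].append(_stage("library", t0, n_compounds=len(library)))

    t0 = time.perf_counter()
    layouts = make_interplate_titration(library, read_days=tuple([0] + config.days),
                                        **config.titration)
    layouts_to_frame(layouts).to_csv(out / "layouts.csv", index=False)
    manifest["stages"].append(_stage("layouts", t0, n_plates=len(layouts)))

    t0 = time.perf_counter()
    dyn = DynamicsConfig(**config.dynamics)
    days = sorted(config.days)
    states = pd.concat(
        [simulate_population(lay, library, days=max(days), params=dyn, seed=config.seed)
         for lay in layouts],
        ignore_index=True,
    )
    read_states = states.loc[states["day"].isin(days)]
    manifest["stages"].append(_stage("simulate", t0, n_well_days=len(read_states)))

    t0 = time.perf_counter()
    optics = OpticsConfig(**config.optics)
    events = emit_lsc_events(read_states, optics, seed=config.seed)
    if write_events:
        events.to_csv(out / "events.csv", index=False)
    gate = GateSpec(**{k: tuple(v) for k, v in config.gate.items()})
    gated = gate_objects(events, gate)
    wells = pd.concat(
        [aggregate_wells(gated, lay, day) for lay in layouts for day in days],
        ignore_index=True,
    )
    wells.to_csv(out / "wells.csv", index=False)
    manifest["stages"].append(
        _stage("gate", t0, n_events=len(events), n_gated=len(gated), n_wells=len(wells))
    )

    t0 = time.perf_counter()
    qc_rows, norm_frames = [], []
    neutral_sds = []
    for (pid, day), plate_wells in wells.groupby(["plate_id", "day"], sort=True):
        for readout in (READOUT_AREA, READOUT_COUNT):
            stats = control_stats(plate_wells, readout)
            qc = plate_quality(stats, plate_id=pid, day=day, readout=readout,
                               sn_mode=config.qc.get("sn_mode", "quadrature"))
            qc_rows.append(vars(qc) | {"n_neutral": stats.n_neutral,
                                       "n_positive": stats.n_positive})
            norm = normalize_wells(plate_wells, stats, readout)
            norm_frames.append(norm)
            window = stats.mu_neutral - stats.mu_positive
            if window != 0:
                neutral_sds.append(100.0 * stats.sigma_neutral / abs(window))
    qc_df = pd.DataFrame(qc_rows)
    qc_df.to_csv(out / "qc.csv", index=False)
    normalized = pd.concat(norm_frames, ignore_index=True)
    normalized.to_csv(out / "normalized.csv", index=False)
    manifest["stages"].append(_stage("qc", t0, n_plate_days=len(qc_df) // 2))
    manifest["qc_summary"] = {
        "median_z_prime": float(qc_df.groupby("readout")["z_prime"].median().round(4).to_dict().get(READOUT_AREA, np.nan)),
        "z_prime_by_readout": {k: round(v, 4) for k, v in qc_df.groupby("readout")["z_prime"].median().to_dict().items()},
    }

    t0 = time.perf_counter()
    series = assemble_series(normalized)
    con = FitConstraints(**config.fit)
    fits = []
    for s in series:
        f = fit_hill(s, con)
        f = mask_outliers(s, f, constraints=con)
        fits.append(f)
    fits_df = fits_to_frame(series, fits)
    fits_df.to_csv(out / "fits.csv", index=False)
    manifest["stages"].append(_stage("fit", t0, n_series=len(series),
                                     n_points=int(sum(len(s) for s in series))))

    t0 = time.perf_counter()
    neutral_sd = float(np.median(neutral_sds)) if neutral_sds else None
    th = ClassThresholds(neutral_sd=neutral_sd, **config.classify)
    calls = [classify_curve(f, s, th) for f, s in zip(fits, series)]
    calls_df = pd.DataFrame([vars(c) for c in calls])
    calls_df["ec50_m"] = fits_df["ec50_m"]
    calls_df.to_csv(out / "classification.csv", index=False)
    by_key = {}
    for c in calls:
        by_key.setdefault((c.readout, c.day), {})[c.compound_id] = c
    d3 = by_key.get((READOUT_AREA, 3), {})
    d7 = by_key.get((READOUT_AREA, max(days)), {})
    priority = prioritize(d3, d7)
    pd.DataFrame([vars(p) for p in priority]).to_csv(out / "priority.csv", index=False)
    manifest["stages"].append(_stage("classify", t0, n_calls=len(calls),
                                     n_active=int(sum(c.is_active for c in calls))))

    t0 = time.perf_counter()
    fp, ids = fingerprint_matrix(library)
    som_cfg = dict(config.som)
    grid = train_som(fp, rows=som_cfg.get("rows"), cols=som_cfg.get("cols"),
                     epochs=som_cfg.get("epochs", 30), seed=config.seed, compound_ids=ids)
    top_final = (config.titration["top_stock"] / config.titration["in_well_dilution"])
    censor = float(np.log10(2.0 * top_final))
    potency = {}
    for c in d7.values():
        row = fits_df.loc[
            (fits_df.compound_id == c.compound_id)
            & (fits_df.readout == READOUT_AREA)
            & (fits_df.day == max(days))
        ]
        if c.is_active and len(row) and np.isfinite(row.iloc[0].log_ec50):
            potency[c.compound_id] = float(row.iloc[0].log_ec50)
        else:
            potency[c.compound_id] = None
    for cid in ids:
        potency.setdefault(cid, None)
    enrich = cluster_enrichment(grid, potency, censor_log_ac50=censor)
    pd.DataFrame(
        [
            {"cluster": e.cluster, "n_members": len(e.member_ids), "t": e.t, "p": e.p,
             "signed_logp": e.signed_logp, "member_ids": ";".join(e.member_ids)}
            for e in enrich
        ]
    ).to_csv(out / "enrichment.csv", index=False)
    heat = enrichment_heatmap(enrich, grid)
    pd.DataFrame(heat).to_csv(out / "enrichment_heatmap.csv", index=False)
    manifest["stages"].append(_stage("enrich", t0, n_clusters=len(enrich),
                                     n_enriched=int(sum(e.testable and e.p < 0.05 and e.signed_logp > 0 for e in enrich))))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
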