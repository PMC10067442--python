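"""Run configuration: one YAML document drives the whole pipeline.

Every stage's parameter block is optional; omitted keys take the package
defaults. Input validation checks CSV schemas (headers, well-name grammar
A01-P24, concentration positivity) and reports violations with line
numbers instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .wells import is_valid_well

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "screen_run",
    "days": [3, 7],
    "library": {"n_compounds": 60, "active_fraction": 0.15, "chemotype_clusters": 8},
    "titration": {
        "n_points": 7,
        "dilution_factor": 5.0,
        "top_stock": 10e-3,
        "in_well_dilution": 240.0,
    },
    "dynamics": {},
    "optics": {},
    "flow": {},
    "gate": {},
    "qc": {"sn_mode": "quadrature"},
    "fit": {},
    "classify": {},
    "som": {"epochs": 30},
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: Path = Path("screen_run")
    days: list[int] = field(default_factory=lambda: [3, 7])
    library: dict = field(default_factory=dict)
    titration: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)
    gate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    som: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        merged = {}
        for key, default in DEFAULTS.items():
            val = raw.get(key, default)
            if isinstance(default, dict):
                val = {**default, **(val or {})}
            merged[key] = val
        unknown = set(raw) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged["out_dir"] = Path(merged["out_dir"])
        merged["days"] = [int(d) for d in merged["days"]]
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


_SCHEMAS: dict[str, list[str]] = {
    "library": ["compound_id", "annotation", "true_ec50_m", "true_hill", "true_efficacy", "fingerprint"],
    "layout": ["plate_id", "well", "role", "compound_id", "conc_m"],
    "events": ["plate_id", "well", "day", "perimeter", "area", "peak_intensity"],
    "flow_events": ["source_well", "day", "tof", "ec", "green"],
    "wells": ["plate_id", "well", "day", "gfp_area_total", "worm_number", "role", "compound_id", "conc_m"],
}


def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Schema-check the given CSVs; keys of ``paths`` name the schema
    (library, layout, events, flow_events, wells).

    Returns a violations table (file, line, message); empty when clean.
    Line numbers are 1-based data rows (header is line 1).
    """
    violations: list[dict] = []

    def flag(fname, line, msg):
        violations.append({"file": str(fname), "line": line, "message": msg})

    for kind, path in paths.items():
        if kind not in _SCHEMAS:
            flag(path, 0, f"unknown input kind {kind!r}")
            continue
        path = Path(path)
        if not path.exists():
            flag(path, 0, "file not found")
            continue
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
        if missing:
            flag(path, 1, f"missing columns: {missing}")
            continue
        if "well" in df.columns:
            for i, w in enumerate(df["well"]):
                if not is_valid_well(w):
                    flag(path, i + 2, f"invalid well name {w!r}")
        for col in ("conc_m", "true_ec50_m"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                for i in vals.index[vals.isna()]:
                    flag(path, i + 2, f"{col}: not a number ({df[col][i]!r})")
                for i in vals.index[vals < 0]:
                    flag(path, i + 2, f"{col}: negative concentration {vals[i]}")
        for col in ("perimeter", "area", "peak_intensity", "tof", "ec"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                for i in vals.index[vals.isna()]:
                    flag(path, i + 2, f"{col}: not a number ({df[col][i]!r})")
                strict = col in ("tof", "ec")
                bad = vals < 0 if not strict else vals <= 0
                for i in vals.index[bad.fillna(False)]:
                    flag(path, i + 2, f"{col}: must be {'positive' if strict else 'non-negative'}")
    return pd.DataFrame(violations, columns=["file", "line", "message"])
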