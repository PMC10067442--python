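"""Synthetic compound libraries with ground-truth pharmacology.

Each compound carries the true parameters of its dose-response effect
(EC50, Hill slope, efficacy, per-stage susceptibility) plus a fixed-length
binary chemotype fingerprint (default 729 bits) drawn with cluster
structure, so that downstream fitting, classification and enrichment can be
validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FINGERPRINT_BITS = 729

# Free-text mechanism labels cycled over the planted actives; purely
# annotation, never consumed by the analysis.
_ACTIVE_MOAS = (
    "anthelmintic (nAChR agonist)",
    "anthelmintic (GluCl agonist)",
    "proteasome inhibitor",
    "antibiotic (protein synthesis)",
    "antifungal (ergosterol)",
    "kinase inhibitor",
)


@dataclass
class CompoundSpec:
    """Ground truth for one synthetic library member.

    ``true_ec50`` is the final in-well molar concentration of half-maximal
    daily kill hazard; ``true_efficacy`` scales the maximal per-day kill
    probability (0 = inert, 1 = full kill at saturation);
    ``stage_susceptibility`` multiplies the hazard per life stage.
    """

    compound_id: str
    annotation: str
    true_ec50: float
    true_hill: float
    true_efficacy: float
    stage_susceptibility: dict[str, float] = field(default_factory=dict)
    fingerprint: np.ndarray = field(default_factory=lambda: np.zeros(FINGERPRINT_BITS, dtype=np.uint8))

    def __post_init__(self) -> None:
        if self.true_ec50 <= 0:
            raise ValueError(f"{self.compound_id}: true_ec50 must be > 0")
        if not 0.0 <= self.true_efficacy <= 1.0:
            raise ValueError(f"{self.compound_id}: true_efficacy must lie in [0, 1]")
        self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)

    @property
    def is_active(self) -> bool:
        return self.true_efficacy > 0


def make_library(
    n_compounds: int,
    active_fraction: float,
    chemotype_clusters: int = 20,
    seed: int = 0,
    *,
    n_bits: int = FINGERPRINT_BITS,
    ec50_range: tuple[float, float] = (5e-8, 5e-6),
    cluster_block_bits: int = 25,
    noise_bits: int = 15,
    steep_fraction: float = 0.25,
    n_active_chemotypes: int | None = None,
) -> list[CompoundSpec]:
    """Draw a seeded library of ``n_compounds`` with ``floor(active_fraction * n)`` actives.

    Active EC50s are log-uniform over ``ec50_range`` (final in-well molar);
    Hill slopes are a mixture of graded (1-2.5, levamisole-like) and steep
    (4-8, ivermectin-like) values. Inactives have ``true_efficacy`` 0.
    Fingerprints share an on-bit block per chemotype cluster plus
    per-compound noise bits, so within-cluster similarity exceeds
    between-cluster similarity.

    ``n_active_chemotypes`` concentrates the actives into that many
    randomly chosen chemotype clusters (filling them first, spillover
    random), emulating libraries where toxicity tracks chemotype — e.g.
    an avermectin cluster that is active wall to wall. The default (None)
    draws actives independently of structure.
    """
    if not isinstance(n_compounds, (int, np.integer)) or isinstance(n_compounds, bool):
        raise TypeError("n_compounds must be an integer")
    if not isinstance(chemotype_clusters, (int, np.integer)) or isinstance(chemotype_clusters, bool):
        raise TypeError("chemotype_clusters must be an integer")
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if chemotype_clusters < 1:
        raise ValueError("chemotype_clusters must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_active = int(np.floor(active_fraction * n_compounds))

    # disjoint on-bit block per chemotype cluster
    block = min(cluster_block_bits, max(1, n_bits // max(chemotype_clusters, 1)))
    perm = rng.permutation(n_bits)
    cluster_bits = [perm[k * block:(k + 1) * block] for k in range(chemotype_clusters)]
    cluster_of = rng.integers(0, chemotype_clusters, size=n_compounds)

    if n_active_chemotypes is None:
        active_idx = set(rng.choice(n_compounds, size=n_active, replace=False).tolist())
    else:
        toxic_clusters = rng.choice(chemotype_clusters,
                                    size=min(n_active_chemotypes, chemotype_clusters),
                                    replace=False)
        pool = rng.permutation(np.flatnonzero(np.isin(cluster_of, toxic_clusters)))
        active_idx = set(pool[:n_active].tolist())
        if len(active_idx) < n_active:
            rest = rng.permutation(np.setdiff1d(np.arange(n_compounds), pool))
            active_idx |= set(rest[: n_active - len(active_idx)].tolist())

    width = max(3, len(str(n_compounds)))
    lo, hi = ec50_range
    library: list[CompoundSpec] = []
    for i in range(n_compounds):
        fp = np.zeros(n_bits, dtype=np.uint8)
        fp[cluster_bits[cluster_of[i]]] = 1
        noise = rng.choice(n_bits, size=min(noise_bits, n_bits), replace=False)
        fp[noise] = 1
        if i in active_idx:
            ec50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if rng.random() < steep_fraction:
                hill = float(rng.uniform(4.0, 8.0))
            else:
                hill = float(rng.uniform(1.0, 2.5))
            efficacy = float(rng.uniform(0.7, 1.0))
            annotation = _ACTIVE_MOAS[i % len(_ACTIVE_MOAS)]
        else:
            ec50, hill, efficacy = 1e-3, 1.0, 0.0
            annotation = "no annotated anti-nematode activity"
        library.append(
            CompoundSpec(
                compound_id=f"CMP{i + 1:0{width}d}",
                annotation=annotation,
                true_ec50=ec50,
                true_hill=hill,
                true_efficacy=efficacy,
                stage_susceptibility={s: 1.0 for s in ("egg", "L1", "L2", "L3", "L4", "adult")},
                fingerprint=fp,
            )
        )
    return library


def library_to_frame(library: list[CompoundSpec]) -> pd.DataFrame:
    """Serialize to the interchange table (fingerprint as a '0'/'1' bitstring)."""
    return pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in library],
            "annotation": [c.annotation for c in library],
            "true_ec50_m": [c.true_ec50 for c in library],
            "true_hill": [c.true_hill for c in library],
            "true_efficacy": [c.true_efficacy for c in library],
            "fingerprint": ["".join(map(str, c.fingerprint.tolist())) for c in library],
        }
    )


def library_from_frame(frame: pd.DataFrame) -> list[CompoundSpec]:
    out = []
    for row in frame.itertuples(index=False):
        fp = np.frombuffer(str(row.fingerprint).encode(), dtype=np.uint8) - ord("0")
        out.append(
            CompoundSpec(
                compound_id=str(row.compound_id),
                annotation=str(row.annotation),
                true_ec50=float(row.true_ec50_m),
                true_hill=float(row.true_hill),
                true_efficacy=float(row.true_efficacy),
                stage_susceptibility={s: 1.0 for s in ("egg", "L1", "L2", "L3", "L4", "adult")},
                fingerprint=fp.astype(np.uint8),
            )
        )
    lengths = {len(c.fingerprint) for c in out}
    if len(lengths) > 1:
        raise ValueError(f"fingerprint lengths differ across library: {sorted(lengths)}")
    return out


def fingerprint_matrix(library: list[CompoundSpec]) -> tuple[np.ndarray, list[str]]:
    """(n_compounds, n_bits) uint8 matrix plus row ids, for SOM training."""
    ids = [c.compound_id for c in library]
    mat = np.stack([c.fingerprint for c in library]).astype(np.uint8)
    return mat, ids
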