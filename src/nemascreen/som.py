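"""Self-organizing-map chemotype clustering and potency enrichment.

Binary substructure fingerprints (729-bit by default) are clustered with a
batch self-organizing map on a rectangular grid: each compound maps to its
nearest prototype (Euclidean distance on the 0/1 vectors) and prototypes
are updated as neighborhood-weighted means with a Gaussian neighborhood
whose radius decays over epochs. Occupied grid units are the structural
clusters ("k<row>.<col>").

Each occupied cluster is then tested for enrichment of potent actives: a
two-sample Welch t-test compares member log-potencies against the whole
library, with inactive compounds imputed at a censoring value above the
top tested concentration. The signed significance -log10(p) (positive =
members more potent than the library average) fills the enrichment heat
map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class SomGrid:
    rows: int
    cols: int
    weights: np.ndarray            # (rows*cols, n_bits)
    assignment: np.ndarray         # unit index per compound
    compound_ids: list[str] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_label(self, unit: int) -> str:
        return f"k{unit // self.cols + 1}.{unit % self.cols + 1}"

    def members(self, unit: int) -> list[str]:
        return [self.compound_ids[i] for i in np.flatnonzero(self.assignment == unit)]


@dataclass
class ClusterEnrichment:
    cluster: str
    unit: int
    member_ids: list[str]
    t: float
    p: float
    signed_logp: float
    mean_member_potency: float
    mean_library_potency: float
    testable: bool


def default_grid_side(n_compounds: int) -> int:
    """Square-grid side giving about 6.5 sqrt(N) units — 14x14 for N~900,
    so occupied-unit counts land in the ~190-cluster regime typical of
    900-compound chemotype maps."""
    return int(np.ceil(np.sqrt(6.5 * np.sqrt(max(n_compounds, 1)))))


def train_som(
    fingerprints: np.ndarray,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 30,
    seed: int = 0,
    compound_ids: list[str] | None = None,
) -> SomGrid:
    """Batch SOM on a rows x cols rectangular grid; deterministic per seed.

    Winners are nearest prototypes by Euclidean distance; prototype updates
    are Gaussian-neighborhood-weighted means with the radius decaying
    linearly from max(rows, cols)/2 to 0.5 across epochs.
    """
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("fingerprints must be a non-empty 2-D matrix")
    n, d = X.shape
    if rows is None or cols is None:
        side = default_grid_side(n)
        rows = rows or side
        cols = cols or side
    units = rows * cols
    if units < 2:
        raise ValueError("grid needs at least 2 units")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    W = X[rng.integers(0, n, size=units)] + rng.uniform(0, 0.05, size=(units, d))

    gy, gx = np.divmod(np.arange(units), cols)
    grid_d2 = (gy[:, None] - gy[None, :]) ** 2 + (gx[:, None] - gx[None, :]) ** 2

    x_sq = (X**2).sum(axis=1)[:, None]
    sigma0 = max(rows, cols) / 2.0
    bmu = np.zeros(n, dtype=int)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 + (0.5 - sigma0) * frac
        d2 = x_sq - 2.0 * X @ W.T + (W**2).sum(axis=1)[None, :]
        bmu = np.argmin(d2, axis=1)
        H = np.exp(-grid_d2 / (2.0 * sigma**2))     # (units, units)
        S = H[bmu]                                   # (n, units) influence of each sample
        denom = S.sum(axis=0)
        numer = S.T @ X
        nonzero = denom > 1e-12
        W[nonzero] = numer[nonzero] / denom[nonzero, None]
    d2 = x_sq - 2.0 * X @ W.T + (W**2).sum(axis=1)[None, :]
    bmu = np.argmin(d2, axis=1)
    return SomGrid(
        rows=rows,
        cols=cols,
        weights=W,
        assignment=bmu,
        compound_ids=list(compound_ids) if compound_ids is not None else [str(i) for i in range(n)],
    )


def cluster_enrichment(
    grid: SomGrid,
    log_ac50: dict[str, float | None],
    censor_log_ac50: float,
    leave_cluster_out: bool = False,
) -> list[ClusterEnrichment]:
    """Welch t-test of member vs library log-potency per occupied unit.

    ``log_ac50`` maps compound -> log10 molar half-maximal concentration or
    None for inactive; inactives are imputed at ``censor_log_ac50``
    (conventionally log10 of twice the top tested concentration). Lower
    log AC50 = more potent; clusters whose members are more potent than the
    library mean get positive ``signed_logp``. Clusters with < 2 members
    are reported untestable, not dropped.
    """
    vals = np.array(
        [log_ac50[c] if log_ac50.get(c) is not None else censor_log_ac50
         for c in grid.compound_ids],
        dtype=float,
    )
    lib_mean = float(vals.mean())
    out: list[ClusterEnrichment] = []
    for unit in range(grid.n_units):
        idx = np.flatnonzero(grid.assignment == unit)
        if idx.size == 0:
            continue
        members = [grid.compound_ids[i] for i in idx]
        mvals = vals[idx]
        ref = vals[np.setdiff1d(np.arange(len(vals)), idx)] if leave_cluster_out else vals
        if idx.size < 2:
            out.append(ClusterEnrichment(
                cluster=grid.unit_label(unit), unit=unit, member_ids=members,
                t=np.nan, p=np.nan, signed_logp=np.nan,
                mean_member_potency=float(mvals.mean()),
                mean_library_potency=lib_mean, testable=False,
            ))
            continue
        t, p = sstats.ttest_ind(mvals, ref, equal_var=False)
        if not np.isfinite(p):
            out.append(ClusterEnrichment(
                cluster=grid.unit_label(unit), unit=unit, member_ids=members,
                t=float(t) if np.isfinite(t) else np.nan, p=np.nan, signed_logp=np.nan,
                mean_member_potency=float(mvals.mean()),
                mean_library_potency=lib_mean, testable=False,
            ))
            continue
        p = max(float(p), 1e-300)  # extreme significance underflows to 0
        sign = 1.0 if mvals.mean() < np.asarray(ref).mean() else -1.0
        out.append(ClusterEnrichment(
            cluster=grid.unit_label(unit), unit=unit, member_ids=members,
            t=float(t), p=float(p), signed_logp=float(sign * -np.log10(p)),
            mean_member_potency=float(mvals.mean()),
            mean_library_potency=lib_mean, testable=True,
        ))
    return out


def enrichment_heatmap(
    enrichments: list[ClusterEnrichment],
    grid: SomGrid,
) -> np.ndarray:
    """(rows, cols) signed -log10(p) matrix; unoccupied or untestable units
    are NaN."""
    mat = np.full((grid.rows, grid.cols), np.nan)
    for e in enrichments:
        if e.testable:
            mat[e.unit // grid.cols, e.unit % grid.cols] = e.signed_logp
    return mat


def permutation_p(
    member_vals: np.ndarray,
    library_vals: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Label-shuffle two-sided p-value for |mean(member) - mean(library)|.

    Independent oracle for the t-test on small instances: permutes which
    compounds form the cluster and recomputes the mean difference.
    """
    rng = np.random.default_rng(seed)
    m = len(member_vals)
    obs = abs(member_vals.mean() - library_vals.mean())
    count = 0
    for _ in range(n_perm):
        pick = rng.choice(len(library_vals), size=m, replace=False)
        if abs(library_vals[pick].mean() - library_vals.mean()) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
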