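"""Spatial resampling test for proximity of marker-positive nuclei.

Per microscope field, the x marker-positive (ORF2p+) nuclei are paired and
their pairwise distances compared with a null built by repeatedly drawing x
nuclei at random (without replacement) from all nuclei in the same field
and pairing them the same way.  Per-pair empirical p-values carry a
Bonferroni factor, and the pooled observed and null distance distributions
are compared with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .stats import TestResult, welch_t

__all__ = [
    "NucleiField",
    "SpatialTestResult",
    "read_nuclei_csv",
    "write_nuclei_csv",
    "observed_pair_distances",
    "null_pair_distances",
    "per_pair_pvalues",
    "compare_distributions",
    "run_proximity_test",
]


@dataclass
class NucleiField:
    """Nuclei centroids (µm) of one microscope field with positive flags."""

    field_id: str
    centroids: np.ndarray        # (n, 2), µm
    positive: np.ndarray         # (n,), bool

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.positive = np.asarray(self.positive, dtype=bool).reshape(-1)
        if len(self.centroids) < 1:
            raise DomainError(f"field {self.field_id!r} has no nuclei")
        if len(self.positive) != len(self.centroids):
            raise DomainError("positive flags must match centroid count")
        if not np.all(np.isfinite(self.centroids)):
            raise DomainError("centroid coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.centroids)

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())


@dataclass
class SpatialTestResult:
    """Full outcome of the nuclei-proximity resampling test."""

    observed_distances: np.ndarray
    null_distances: np.ndarray
    per_pair_p: np.ndarray
    welch: TestResult
    n_resamples: int
    seed: int
    pairing: str
    bonferroni_m: int
    skipped_fields: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observed_distances_um": self.observed_distances.tolist(),
            "n_null_distances": int(len(self.null_distances)),
            "per_pair_p": self.per_pair_p.tolist(),
            "welch_t": self.welch.statistic,
            "welch_df": self.welch.df,
            "welch_p": self.welch.p_value,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "pairing": self.pairing,
            "bonferroni_m": self.bonferroni_m,
            "skipped_fields": self.skipped_fields,
        }


def read_nuclei_csv(path) -> list[NucleiField]:
    """Load fields from a CSV with columns field_id, x_um, y_um, positive."""
    df = pd.read_csv(path)
    required = {"field_id", "x_um", "y_um", "positive"}
    if not required.issubset(df.columns):
        raise DomainError(f"nuclei CSV must have columns {sorted(required)}")
    fields = []
    for fid, grp in df.groupby("field_id", sort=True):
        fields.append(
            NucleiField(
                str(fid),
                grp[["x_um", "y_um"]].to_numpy(dtype=float),
                grp["positive"].to_numpy().astype(bool),
            )
        )
    return fields


def write_nuclei_csv(fields: list[NucleiField], path) -> None:
    rows = []
    for f in fields:
        for (x, y), pos in zip(f.centroids, f.positive):
            rows.append({"field_id": f.field_id, "x_um": x, "y_um": y,
                         "positive": int(pos)})
    pd.DataFrame(rows).to_csv(path, index=False)


def _pair_distances(points: np.ndarray, rule: str) -> np.ndarray:
    """Distances of the pairs formed among ``points`` under the pairing rule.

    "mutual_nn": mutual nearest neighbours, one distance per reciprocal
    pair (the default reading of "pairs of positive nuclei");
    "all_pairs": every pairwise distance; "greedy": repeatedly extract the
    closest remaining pair.
    """
    m = len(points)
    if m < 2:
        return np.empty(0)
    diff = points[:, None, :] - points[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    if rule == "all_pairs":
        return D[np.triu_indices(m, k=1)]
    if rule == "mutual_nn":
        np.fill_diagonal(D, np.inf)
        nn = D.argmin(axis=1)
        out = [D[i, nn[i]] for i in range(m) if nn[nn[i]] == i and i < nn[i]]
        return np.asarray(out)
    if rule == "greedy":
        np.fill_diagonal(D, np.inf)
        alive = np.ones(m, dtype=bool)
        out = []
        while alive.sum() >= 2:
            sub = np.where(alive)[0]
            block = D[np.ix_(sub, sub)]
            i, j = np.unravel_index(block.argmin(), block.shape)
            out.append(block[i, j])
            alive[sub[i]] = alive[sub[j]] = False
        return np.asarray(out)
    raise DomainError(f"unknown pairing rule {rule!r}")


def observed_pair_distances(
    fields: list[NucleiField], pairing: str = "mutual_nn"
) -> tuple[np.ndarray, list[str]]:
    """Pooled pair distances of positive nuclei; fields with <2 positives skipped."""
    out, skipped = [], []
    for f in fields:
        if f.n_positive < 2:
            skipped.append(f.field_id)
            continue
        out.append(_pair_distances(f.centroids[f.positive], pairing))
    if not out:
        raise InsufficientDataError("no field has >= 2 positive nuclei")
    return np.concatenate(out), skipped


def null_pair_distances(
    fields: list[NucleiField],
    n_resamples: int = 1000,
    seed: int = 0,
    pairing: str = "mutual_nn",
) -> np.ndarray:
    """Null distances: per field, per round, pair x randomly chosen nuclei.

    Sampling is without replacement within the field, matching each field's
    positive count x, and the same pairing rule is applied as for the
    observed positives.
    """
    rng = np.random.default_rng(seed)
    pooled = []
    for f in fields:
        x = f.n_positive
        if x < 2:
            continue
        assert x <= f.n
        for _ in range(n_resamples):
            idx = rng.choice(f.n, size=x, replace=False)
            pooled.append(_pair_distances(f.centroids[idx], pairing))
    if not pooled:
        raise InsufficientDataError("no field has >= 2 positive nuclei")
    return np.concatenate(pooled)


def per_pair_pvalues(observed, null, m: int | None = None) -> np.ndarray:
    """Bonferroni-corrected add-one empirical p per observed pair distance.

    p_raw = (1 + #{null <= observed}) / (1 + #null); p = min(1, m * p_raw)
    with m defaulting to the number of observed pairs.
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.sort(np.asarray(null, dtype=float))
    if nul.size == 0:
        raise InsufficientDataError("null distribution is empty")
    if m is None:
        m = obs.size
    counts = np.searchsorted(nul, obs, side="right")
    p_raw = (1.0 + counts) / (1.0 + nul.size)
    return np.minimum(1.0, m * p_raw)


def compare_distributions(observed, null) -> TestResult:
    """Welch's t-test of the observed vs null pooled distance distributions."""
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size < 2 or nul.size < 2:
        raise InsufficientDataError("both distance lists need >= 2 values")
    return welch_t(obs, nul)


def run_proximity_test(
    fields: list[NucleiField],
    n_resamples: int = 1000,
    seed: int = 0,
    pairing: str = "mutual_nn",
) -> SpatialTestResult:
    """Observed vs resampled nuclei-pair distances with all summary statistics."""
    observed, skipped = observed_pair_distances(fields, pairing=pairing)
    null = null_pair_distances(
        fields, n_resamples=n_resamples, seed=seed, pairing=pairing
    )
    pvals = per_pair_pvalues(observed, null)
    welch = compare_distributions(observed, null)
    return SpatialTestResult(
        observed_distances=observed,
        null_distances=null,
        per_pair_p=pvals,
        welch=welch,
        n_resamples=n_resamples,
        seed=seed,
        pairing=pairing,
        bonferroni_m=int(observed.size),
        skipped_fields=skipped,
    )
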