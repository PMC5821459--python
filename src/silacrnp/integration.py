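"""Multi-assay distance integration and final clustering.

Each assay (RNase sensitivity, split-tandem, EN/RT mutants, exchange
kinetics) contributes a per-protein profile vector.  For every protein pair
the profiles of the experiments both proteins appear in are concatenated,
yielding a Euclidean and a cosine distance; Euclidean distances are min-max
rescaled onto (0, 0.9], pairs with no shared experiment are assigned a
Euclidean component of exactly 1, and the two components are fused as
d = log(E' * C), finally min-max rescaled onto [0, 1].  The log-product is a
monotone transform of E'*C, so the fused distance preserves the product's
ranking while compressing its dynamic range.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .stats import Dendrogram, DistanceMatrix, cosine_distance, hierarchical_cluster

__all__ = [
    "ExperimentProfileSet",
    "IntegratedDistance",
    "pair_component_distances",
    "rescale_euclidean",
    "assign_missing",
    "combine_and_rescale",
    "integrate",
    "integrate_and_cluster",
]

#: lower endpoint of the "open" rescaling intervals; keeps log() finite
DEFAULT_DELTA = 1e-3


@dataclass
class ExperimentProfileSet:
    """Named per-experiment profile matrices over a common protein universe.

    ``experiments`` maps an experiment name to a proteins x features frame;
    a protein absent from an experiment is simply missing from that frame's
    index.  ``standardize`` z-scores each feature column within its
    experiment before distances are computed, keeping heterogeneous assay
    scales commensurate (raw mode is available for scale-faithful input).
    """

    experiments: dict[str, pd.DataFrame]
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.experiments:
            raise DomainError("at least one experiment is required")
        for name, df in self.experiments.items():
            if df.empty:
                raise DomainError(f"experiment {name!r} has no proteins")

    @property
    def universe(self) -> list[str]:
        labs: set[str] = set()
        for df in self.experiments.values():
            labs.update(df.index)
        return sorted(labs)

    def prepared(self) -> dict[str, pd.DataFrame]:
        """Experiment frames after optional per-column standardization."""
        out = {}
        for name, df in self.experiments.items():
            if self.standardize:
                sd = df.std(ddof=0).replace(0.0, 1.0)
                out[name] = (df - df.mean()) / sd
            else:
                out[name] = df.astype(float)
        return out


@dataclass
class IntegratedDistance:
    """Per-pair component and fused distances plus the final matrix."""

    pairs: pd.DataFrame  # protein_a, protein_b, euclidean, rescaled_euclidean,
                         # cosine, shared_experiments, missing, d
    matrix: DistanceMatrix
    delta: float

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)


def pair_component_distances(profiles: ExperimentProfileSet) -> pd.DataFrame:
    """Euclidean and cosine distance per pair over the shared experiments.

    The experiments both proteins appear in are concatenated into one
    vector per protein before the distances are taken; pairs with no
    shared experiment are flagged missing (components NaN at this stage).
    """
    prep = profiles.prepared()
    universe = profiles.universe
    rows = []
    for a, b in itertools.combinations(universe, 2):
        va, vb, shared = [], [], 0
        for name, df in prep.items():
            if a in df.index and b in df.index:
                va.append(df.loc[a].to_numpy(dtype=float))
                vb.append(df.loc[b].to_numpy(dtype=float))
                shared += 1
        if shared == 0:
            rows.append((a, b, np.nan, np.nan, 0, True))
            continue
        ua, ub = np.concatenate(va), np.concatenate(vb)
        euc = float(np.linalg.norm(ua - ub))
        if np.linalg.norm(ua) == 0.0 or np.linalg.norm(ub) == 0.0:
            cos = 1.0  # direction undefined; treat as maximally dissimilar
        else:
            cos = cosine_distance(ua, ub)
        rows.append((a, b, euc, cos, shared, False))
    return pd.DataFrame(
        rows,
        columns=["protein_a", "protein_b", "euclidean", "cosine",
                 "shared_experiments", "missing"],
    )


def rescale_euclidean(values, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """Min-max map of observed Euclidean distances onto [delta, 0.9].

    ``delta`` realizes the open lower endpoint of the (0, 0.9) target range;
    a literal 0 would make the subsequent log undefined.  NaN (missing-pair)
    entries pass through untouched.
    """
    v = np.asarray(values, dtype=float)
    obs = v[np.isfinite(v)]
    if obs.size < 2:
        raise DomainError("need >= 2 observed Euclidean distances to rescale")
    lo, hi = obs.min(), obs.max()
    out = v.copy()
    if lo == hi:
        out[np.isfinite(v)] = 0.9
        return out
    m = np.isfinite(v)
    out[m] = delta + (v[m] - lo) * (0.9 - delta) / (hi - lo)
    return out


def assign_missing(pairs: pd.DataFrame) -> pd.DataFrame:
    """Give no-shared-experiment pairs a rescaled Euclidean component of 1.

    Their cosine component is set to 1 as well so the fused distance is
    defined; this places such pairs at the far end of the scale.
    """
    out = pairs.copy()
    miss = out["missing"]
    out.loc[miss, "rescaled_euclidean"] = 1.0
    out.loc[miss, "cosine"] = 1.0
    return out


def combine_and_rescale(pairs: pd.DataFrame, delta: float = DEFAULT_DELTA) -> pd.DataFrame:
    """Fuse components as log(E' * max(C, delta)) and min-max rescale onto [0, 1]."""
    out = pairs.copy()
    e = out["rescaled_euclidean"].to_numpy(dtype=float)
    c = np.maximum(out["cosine"].to_numpy(dtype=float), delta)
    raw = np.log(e * c)
    lo, hi = raw.min(), raw.max()
    out["d"] = 0.0 if lo == hi else (raw - lo) / (hi - lo)
    return out


def integrate(
    profiles: ExperimentProfileSet, delta: float = DEFAULT_DELTA
) -> IntegratedDistance:
    """Run the full component -> rescale -> assign-missing -> fuse chain."""
    pairs = pair_component_distances(profiles)
    pairs["rescaled_euclidean"] = rescale_euclidean(pairs["euclidean"], delta=delta)
    pairs = assign_missing(pairs)
    pairs = combine_and_rescale(pairs, delta=delta)
    universe = profiles.universe
    pos = {lab: i for i, lab in enumerate(universe)}
    n = len(universe)
    mat = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for row in pairs.itertuples(index=False):
        i, j = pos[row.protein_a], pos[row.protein_b]
        mat[i, j] = mat[j, i] = row.d
        mask[i, j] = mask[j, i] = row.missing
    return IntegratedDistance(
        pairs=pairs,
        matrix=DistanceMatrix(universe, mat),
        delta=delta,
    )


def integrate_and_cluster(
    profiles: ExperimentProfileSet,
    k: int = 5,
    linkage: str = "average",
    delta: float = DEFAULT_DELTA,
) -> tuple[pd.Series, Dendrogram, IntegratedDistance]:
    """Cluster the fused distance matrix into ``k`` protein groups."""
    result = integrate(profiles, delta=delta)
    if k > result.matrix.n:
        raise DomainError(f"k={k} exceeds the {result.matrix.n} proteins available")
    dendro = hierarchical_cluster(result.matrix, linkage=linkage)
    return dendro.cut(k), dendro, result
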