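"""Exchange kinetics of bait-bound proteins challenged with light extract.

Heavy-labelled, in-vivo-assembled complexes immobilized on the affinity
medium are incubated with light-labelled extract; the per-protein heavy
fraction h(t) at {0, 30, 300, 1800} s traces how fast each interactor is
replaced.  Trajectory shapes are compared by cosine distance (amplitude
invariant) and grouped by hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError, InsufficientDataError
from .stats import Dendrogram, DistanceMatrix, cosine_distance, hierarchical_cluster

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "require_complete",
    "pairwise_exchange_distance",
    "cluster_exchange",
    "distance_trajectory",
]

#: assay schedule in seconds: capture, 30 s, 5 min, 30 min
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 30.0, 300.0, 1800.0)


def require_complete(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Keep only proteins quantified at every time point.

    ``matrix``: proteins x time points (columns are times, ascending).
    Returns the complete submatrix and the dropped protein labels.
    """
    times = [float(c) for c in matrix.columns]
    if times != sorted(times) or len(set(times)) != len(times):
        raise DomainError("time points must be strictly increasing")
    complete = matrix.dropna(axis=0)
    dropped = sorted(set(matrix.index) - set(complete.index))
    if complete.empty:
        raise InsufficientDataError("no protein is complete across all time points")
    return complete, dropped


def pairwise_exchange_distance(
    matrix: pd.DataFrame,
) -> tuple[DistanceMatrix, list[str]]:
    """Cosine distances between all protein trajectory pairs.

    All-zero trajectories (cosine undefined) are excluded and reported.
    """
    norms = np.linalg.norm(matrix.to_numpy(dtype=float), axis=1)
    excluded = sorted(matrix.index[norms == 0.0])
    kept = matrix.loc[norms > 0.0]
    if len(kept) < 2:
        raise InsufficientDataError("need >= 2 proteins with non-zero trajectories")
    d = squareform(pdist(kept.to_numpy(dtype=float), metric="cosine"))
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(kept.index), d), excluded


def cluster_exchange(
    matrix: pd.DataFrame, k: int = 3, linkage: str = "average"
) -> tuple[pd.Series, Dendrogram]:
    """Cut the trajectory dendrogram into ``k`` kinetic classes.

    Classes are renumbered by decreasing mean terminal heavy fraction, so
    cluster 1 is the most exchange-stable group.
    """
    if k > len(matrix):
        raise DomainError(f"k={k} exceeds the {len(matrix)} proteins available")
    dmat, _ = pairwise_exchange_distance(matrix)
    dendro = hierarchical_cluster(dmat, linkage=linkage)
    raw = dendro.cut(k)
    terminal = matrix.loc[raw.index].iloc[:, -1]
    order = (
        terminal.groupby(raw).mean().sort_values(ascending=False).index.tolist()
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = raw.map(remap).rename("cluster")
    return labels, dendro


def distance_trajectory(matrix: pd.DataFrame, pair: tuple[str, str]) -> pd.Series:
    """Cumulative-prefix cosine distances of one protein pair over time.

    For each prefix t_1..t_j (j >= 2) the cosine distance between the two
    prefix vectors is reported, indexed by the prefix's last time point.
    This cumulative-prefix construction is one of several possible
    time-resolved readings and is labelled as such in pipeline metadata.
    """
    a, b = pair
    for p in (a, b):
        if p not in matrix.index:
            raise DomainError(f"protein {p!r} absent from the time-course matrix")
    va = matrix.loc[a].to_numpy(dtype=float)
    vb = matrix.loc[b].to_numpy(dtype=float)
    out = {}
    for j in range(2, len(matrix.columns) + 1):
        out[float(matrix.columns[j - 1])] = cosine_distance(va[:j], vb[:j])
    return pd.Series(out, name=f"{a}|{b}")
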