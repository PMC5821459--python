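"""Split-tandem partition profiles and cluster-proximity probabilities.

In split-tandem capture the bait-tagged complexes are re-captured against a
second component (ORF1p), splitting each protein between a bound (elution)
and unbound (supernatant) population; the per-protein elution fraction on
each label-swap axis is the co-partitioning coordinate.  Coordinates are
re-expressed on an anchor scale (ORF1p = 1, population median preserved),
and the tightness of a designated k-protein cluster is scored against the
empirical distribution of all k-subsets of the plotted proteins.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateError, DomainError
from .quant_io import SwapPairCoordinates

__all__ = [
    "PartitionTable",
    "ClusterProximityResult",
    "normalize_to_anchor",
    "cluster_proximity",
    "cluster_proximity_pvalue",
]

_AXES = ("x", "y")
_ANCHOR_TOL = 1e-3


@dataclass
class PartitionTable:
    """Anchor-normalized partition coordinates.

    Per axis the affine map f(v) = a*v + b satisfies f(anchor) = 1 and
    f(median) = median, so the anchor reads exactly 1 while the bulk of the
    distribution keeps its location.
    """

    raw: pd.DataFrame         # protein, x, y (elution fractions)
    normalized: pd.DataFrame  # protein, x, y (anchor scale)
    anchor: str
    affine: dict[str, tuple[float, float]]  # axis -> (a, b)


@dataclass
class ClusterProximityResult:
    """A k-member cluster, its proximity, and its empirical probability."""

    members: tuple[str, ...]
    k: int
    proximity: float
    n_universe: int
    p_empirical: float
    method: str                      # "exact" | "monte_carlo"
    metric: str
    n_samples: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "k": self.k,
            "proximity": self.proximity,
            "n_universe": self.n_universe,
            "p_empirical": self.p_empirical,
            "method": self.method,
            "metric": self.metric,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def normalize_to_anchor(
    coords: SwapPairCoordinates | pd.DataFrame, anchor: str
) -> PartitionTable:
    """Affine-rescale each swap axis so the anchor protein maps to 1.

    Solves f(v_anchor) = 1 and f(median) = median per axis; ill-defined when
    the anchor sits at (or numerically near) the median, since no affine map
    can separate the two constraints — that raises :class:`DegenerateError`.
    """
    raw = (coords.df if isinstance(coords, SwapPairCoordinates) else coords).copy()
    if anchor not in set(raw["protein"]):
        raise DomainError(f"anchor {anchor!r} absent from coordinates")
    normalized = raw.copy()
    affine: dict[str, tuple[float, float]] = {}
    anchor_row = raw.set_index("protein").loc[anchor]
    for axis in _AXES:
        v = raw[axis].to_numpy(dtype=float)
        m = float(np.median(v))
        va = float(anchor_row[axis])
        if abs(va - m) < _ANCHOR_TOL:
            raise DegenerateError(
                f"anchor value equals the median on axis {axis!r}; affine map ill-defined"
            )
        a = (1.0 - m) / (va - m)
        b = m * (1.0 - a)
        # centered form a*(v - m) + m: algebraically a*v + b, but exact at
        # the median and well-conditioned when the anchor sits near it
        normalized[axis] = a * (v - m) + m
        affine[axis] = (a, b)
    return PartitionTable(raw=raw, normalized=normalized, anchor=anchor, affine=affine)


def _pairwise(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _proximity_from_matrix(D: np.ndarray, idx, metric: str, points: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    pair_d = sub[iu]
    if metric == "diameter":
        return float(pair_d.max())
    if metric == "mean_pairwise":
        return float(pair_d.mean())
    if metric == "enclosing_radius":
        return _enclosing_radius(points[list(idx)])
    raise DomainError(f"unknown proximity metric {metric!r}")


def _enclosing_radius(pts: np.ndarray) -> float:
    """Radius of the smallest circle enclosing <= 3 points (exact small cases)."""
    if len(pts) == 1:
        return 0.0
    if len(pts) == 2:
        return float(np.linalg.norm(pts[0] - pts[1]) / 2.0)
    best = 0.0
    # check all pair-diameter circles, then the circumcircle
    for i, j in itertools.combinations(range(len(pts)), 2):
        c = (pts[i] + pts[j]) / 2.0
        r = float(np.linalg.norm(pts[i] - pts[j]) / 2.0)
        if np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-12):
            return r
    a, b, c = pts[:3]
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-15:  # collinear
        iu = _pairwise(pts)[np.triu_indices(3, k=1)]
        return float(iu.max() / 2.0)
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
    center = np.array([ux, uy])
    return float(np.linalg.norm(pts - center, axis=1).max())


def cluster_proximity(
    points: pd.DataFrame, members, metric: str = "diameter"
) -> float:
    """Tightness of the ``members`` set in the (x, y) plane.

    ``metric``: "diameter" (max pairwise distance, default), "mean_pairwise",
    or "enclosing_radius".
    """
    idx = points.set_index("protein")
    members = list(members)
    missing = [m for m in members if m not in idx.index]
    if missing:
        raise DomainError(f"cluster members absent from points: {missing}")
    pts = idx.loc[members, list(_AXES)].to_numpy(dtype=float)
    D = _pairwise(pts)
    return _proximity_from_matrix(D, list(range(len(members))), metric, pts)


def cluster_proximity_pvalue(
    points: pd.DataFrame,
    members,
    mode: str = "exact",
    n_samples: int = 100_000,
    seed: int | None = None,
    metric: str = "diameter",
    exact_cap: int = 10**8,
) -> ClusterProximityResult:
    """Empirical probability that a random k-subset is as tight as ``members``.

    Exact mode enumerates all C(n, k) subsets (inclusive ties, and the
    observed subset counts itself, so p is never 0).  Monte-Carlo mode draws
    ``n_samples`` uniform k-subsets and applies the add-one rule.
    """
    members = tuple(members)
    k = len(members)
    labels = points["protein"].tolist()
    n = len(labels)
    if k < 2:
        raise DomainError("cluster must have k >= 2 members")
    if n < k:
        raise DomainError(f"universe of {n} proteins cannot host a {k}-cluster")
    pts = points[list(_AXES)].to_numpy(dtype=float)
    D = _pairwise(pts)
    pos = {lab: i for i, lab in enumerate(labels)}
    try:
        member_idx = [pos[m] for m in members]
    except KeyError as exc:
        raise DomainError(f"cluster member {exc.args[0]!r} absent from universe") from exc
    observed = _proximity_from_matrix(D, member_idx, metric, pts)

    if mode == "exact":
        total = math.comb(n, k)
        if total > exact_cap:
            raise DomainError(
                f"C({n},{k}) = {total} exceeds the exact-enumeration cap; use monte_carlo"
            )
        if metric in ("diameter", "mean_pairwise"):
            pair_pos = list(itertools.combinations(range(k), 2))
            count = 0
            it = itertools.combinations(range(n), k)
            chunk = 1_000_000
            while True:
                flat = np.fromiter(
                    itertools.chain.from_iterable(itertools.islice(it, chunk)),
                    dtype=np.intp,
                )
                if flat.size == 0:
                    break
                combos = flat.reshape(-1, k)
                pair_d = np.stack(
                    [D[combos[:, i], combos[:, j]] for i, j in pair_pos], axis=1
                )
                prox = (
                    pair_d.max(axis=1) if metric == "diameter" else pair_d.mean(axis=1)
                )
                count += int(np.sum(prox <= observed + 1e-12))
        else:
            count = 0
            for combo in itertools.combinations(range(n), k):
                if _proximity_from_matrix(D, combo, metric, pts) <= observed + 1e-12:
                    count += 1
        p = count / total
        return ClusterProximityResult(
            members, k, observed, n, p, method="exact", metric=metric
        )

    if mode != "monte_carlo":
        raise DomainError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    count = 0
    batch = 20_000
    done = 0
    pair_pos = list(itertools.combinations(range(k), 2))
    while done < n_samples:
        b = min(batch, n_samples - done)
        # uniform k-subsets via partial argsort of random keys
        keys = rng.random((b, n))
        subsets = np.argpartition(keys, k, axis=1)[:, :k]
        if metric in ("diameter", "mean_pairwise"):
            pair_d = np.stack(
                [D[subsets[:, i], subsets[:, j]] for i, j in pair_pos], axis=1
            )
            prox = pair_d.max(axis=1) if metric == "diameter" else pair_d.mean(axis=1)
            count += int(np.sum(prox <= observed + 1e-12))
        else:
            for row in subsets:
                if _proximity_from_matrix(D, row.tolist(), metric, pts) <= observed + 1e-12:
                    count += 1
        done += b
    p = (1 + count) / (1 + n_samples)
    return ClusterProximityResult(
        members, k, observed, n, p,
        method="monte_carlo", metric=metric, n_samples=n_samples, seed=seed,
    )
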