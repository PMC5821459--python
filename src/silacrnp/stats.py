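"""Shared statistical primitives: t-tests, BH correction, distances, clustering.

Every downstream stage draws its inference machinery from here so that
conventions (two-sided p-values, average linkage, Newick serialization) are
applied uniformly.  The heavy lifting is delegated to scipy/statsmodels; the
surface exposed here is the contract the rest of the pipeline programs
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError

__all__ = [
    "TestResult",
    "DistanceMatrix",
    "Dendrogram",
    "normal_upper_quantile",
    "one_sample_t",
    "welch_t",
    "bh_adjust",
    "cosine_distance",
    "hierarchical_cluster",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a location test.

    ``degenerate`` marks zero-variance inputs for which the statistic is
    undefined; such results carry ``p_value = nan`` and must be excluded
    from any multiple-testing family.
    """

    statistic: float
    df: float
    p_value: float
    two_sided: bool = True
    degenerate: bool = False


def normal_upper_quantile(alpha: float) -> float:
    """Return z such that P(Z > z) = ``alpha`` for standard normal Z."""
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha!r}")
    return float(_sps.norm.isf(alpha))


def one_sample_t(values, mu0: float, two_sided: bool = True) -> TestResult:
    """One-sample t-test of mean(values) against ``mu0``.

    Returns a degenerate result (p = nan) when the sample variance is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("one_sample_t needs at least 2 values")
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0.0:
        return TestResult(np.nan, float(n - 1), np.nan, two_sided, degenerate=True)
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = float(n - 1)
    p = 2.0 * _sps.t.sf(abs(t), df) if two_sided else _sps.t.sf(t, df)
    return TestResult(float(t), df, float(min(p, 1.0)), two_sided)


def welch_t(a, b, equal_var: bool = False, two_sided: bool = True) -> TestResult:
    """Two-sample t-test; Welch (unequal variances) by default.

    ``equal_var=True`` selects the classical pooled-variance statistic.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("welch_t needs at least 2 values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(nx + ny - 2), 1.0, two_sided)
        return TestResult(np.nan, float(nx + ny - 2), np.nan, two_sided, degenerate=True)
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = float(nx + ny - 2)
    else:
        wx, wy = vx / nx, vy / ny
        se = np.sqrt(wx + wy)
        # Welch-Satterthwaite on normalized weights: scale-invariant, so the
        # ratio cannot underflow for extreme variance magnitudes
        m = max(wx, wy)
        rx, ry = wx / m, wy / m
        df = (rx + ry) ** 2 / (rx**2 / (nx - 1) + ry**2 / (ny - 1))
    t = (x.mean() - y.mean()) / se
    p = 2.0 * _sps.t.sf(abs(t), df) if two_sided else _sps.t.sf(t, df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), two_sided)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cosine_distance(u, v) -> float:
    """1 − cosine similarity of two equal-length vectors."""
    x = np.asarray(u, dtype=float)
    y = np.asarray(v, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise DomainError("cosine_distance needs two equal-length 1-D vectors")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise DomainError("cosine distance undefined for an all-zero vector")
    d = 1.0 - float(np.dot(x, y) / (nx * ny))
    # guard against tiny negative round-off for proportional vectors
    return 0.0 if abs(d) < 1e-15 else d


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with protein labels.

    ``mask`` (optional boolean matrix) marks pairs whose distance is not
    backed by any shared observation (see the integration stage).
    """

    labels: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DomainError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise DomainError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise DomainError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) over labelled leaves."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str = "average"

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cut(self, k: int) -> pd.Series:
        """Cut into ``k`` flat clusters; returns integer labels (1..k) per leaf."""
        if not 1 <= k <= len(self.labels):
            raise DomainError(f"k must be in [1, {len(self.labels)}]")
        assign = _hier.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths = differences of merge heights."""
        tree = _hier.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a complete distance matrix.

    Missing pairs must be resolved (imputed or assigned) before clustering;
    the integration stage does this with its fixed missing-pair distance.
    """
    if d.mask is not None and np.any(d.mask[np.triu_indices(d.n, k=1)]):
        raise DomainError(
            "distance matrix has missing pairs; assign missing-pair distances first"
        )
    if not np.all(np.isfinite(d.values)):
        raise DomainError("distance matrix contains non-finite entries")
    Z = _hier.linkage(d.condensed(), method=linkage)
    return Dendrogram(list(d.labels), Z, method=linkage)
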