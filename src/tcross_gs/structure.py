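"""Population structure: Rogers genetic distances, principal coordinate
analysis and K-means clustering with Caliński–Harabasz model selection.

Rogers' distance between two lines averages, over loci, the Euclidean
distance between their within-individual allele-frequency vectors scaled to
[0, 1]. For additively coded calls x in [-1, +1] (homozygotes ±1, a
heterozygote or mean-imputed call anywhere in between) the per-locus
frequency of the "+" allele is p = (x+1)/2 and the per-locus term
sqrt(0.5 * ((p_i-p_j)^2 + ((1-p_i)-(1-p_j))^2)) collapses to |x_i - x_j| / 2,
so the full matrix is a scaled Manhattan distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    line_ids: list
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.line_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match line ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.line_ids, columns=self.line_ids)


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # lines x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    explained_variance_pct: np.ndarray  # per returned axis
    line_ids: list


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    ch_score: float
    seed: int
    inertia: float

    def sizes(self) -> list[int]:
        return list(np.bincount(self.labels, minlength=self.k))


def rogers_distance(genotypes: GenotypeMatrix | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Rogers distances among lines from the coded marker matrix."""
    coded = genotypes.coded if isinstance(genotypes, GenotypeMatrix) else genotypes
    x = coded.to_numpy(dtype=float)
    if x.shape[1] == 0:
        raise ValueError("no markers: Rogers distance undefined")
    # per-locus term |x_i - x_j|/2, averaged over loci
    d = squareform(pdist(x, metric="cityblock")) / (2.0 * x.shape[1])
    return DistanceMatrix(line_ids=list(coded.index), d=d)


def pcoa(dist: DistanceMatrix, n_axes: int = 4) -> PCoAResult:
    """Classical MDS of a distance matrix via Gower double-centering.

    Coordinates are eigenvectors of -0.5 * J D^2 J scaled by the square root
    of their (positive) eigenvalues; negative eigenvalues — possible because
    Rogers distances need not be Euclidean — are excluded from both the
    coordinates and the explained-variance denominator.
    """
    d = dist.d
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    tol = max(abs(vals[0]), 1.0) * 1e-12 if vals.size else 0.0
    pos = vals > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        warnings.warn("all PCoA eigenvalues are zero; explained variance undefined")
        axes = min(n_axes, n)
        return PCoAResult(
            coordinates=np.zeros((n, axes)),
            eigenvalues=vals,
            explained_variance_pct=np.zeros(axes),
            line_ids=dist.line_ids,
        )
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
        n_axes = n_pos
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    pct = 100.0 * vals[:n_axes] / vals[pos].sum()
    return PCoAResult(
        coordinates=coords,
        eigenvalues=vals,
        explained_variance_pct=pct,
        line_ids=dist.line_ids,
    )


def calinski_harabasz(coords: np.ndarray, labels: np.ndarray) -> float:
    """Caliński–Harabasz index: [B/(k-1)] / [W/(n-k)].

    B and W are the between- and within-cluster sums of squared deviations
    about centroids.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = uniq.size, coords.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters")
    grand = coords.mean(axis=0)
    b = w = 0.0
    for u in uniq:
        pts = coords[labels == u]
        if pts.shape[0] == 0:
            raise ValueError(f"empty cluster {u!r}")
        c = pts.mean(axis=0)
        b += pts.shape[0] * float(((c - grand) ** 2).sum())
        w += float(((pts - c) ** 2).sum())
    if w == 0.0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


def kmeans_cluster(
    pcoa_result: PCoAResult,
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
) -> ClusterSolution:
    """K-means (Lloyd, k-means++ seeding, best of ``n_restarts`` starts)."""
    coords = pcoa_result.coordinates
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of lines ({n})")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        init="k-means++",
        algorithm="lloyd",
        random_state=seed,
    ).fit(coords)
    try:
        ch = calinski_harabasz(coords, km.labels_)
    except ValueError:
        ch = np.nan
    return ClusterSolution(
        k=k,
        labels=km.labels_,
        centroids=km.cluster_centers_,
        ch_score=float(ch),
        seed=seed,
        inertia=float(km.inertia_),
    )


def select_k(
    pcoa_result: PCoAResult,
    k_range=range(2, 9),
    n_restarts: int = 50,
    seed: int = 0,
) -> tuple[int, ClusterSolution]:
    """Pick the k maximizing the Caliński–Harabasz index over ``k_range``.

    Ties break to the smallest k (strict improvement required to switch).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    best: ClusterSolution | None = None
    for k in ks:
        sol = kmeans_cluster(pcoa_result, k, n_restarts=n_restarts, seed=seed)
        logger.info("select_k: k=%d CH=%.3f", k, sol.ch_score)
        if best is None or sol.ch_score > best.ch_score:
            best = sol
    assert best is not None
    return best.k, best


def cluster_labels_series(solution: ClusterSolution, line_ids) -> pd.Series:
    """Cluster labels as 'C1'..'Ck', ordered by descending cluster size."""
    sizes = np.bincount(solution.labels, minlength=solution.k)
    rank = {c: i for i, c in enumerate(np.argsort(sizes)[::-1])}
    return pd.Series(
        [f"C{rank[c] + 1}" for c in solution.labels], index=line_ids, name="cluster"
    )
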