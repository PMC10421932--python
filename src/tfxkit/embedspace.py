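"""Protein feature vectors, UMAP projection, clustering, and concordance.

Feature modes: 20D amino-acid composition, 400D normalized 2-mer counts, a
16D cysteine-framework descriptor, or imported (e.g. mean-pooled protein
language model) vectors. Vectors are projected to 3D with UMAP
(n_neighbors=25, min_dist=0.5, n_components=3, fixed seed) and clustered
with k-means (k=7), DBSCAN (eps=0.55, min_pts=5) and OPTICS (xi=0.01);
partition agreement is quantified by the adjusted Rand index with noise
treated as one extra class.

DBSCAN and the OPTICS reachability ordering are implemented here because
their tie-breaking rules (border points to the lowest cluster index; next
point by minimum reachability then lowest index) are part of the contract
and are validated against independent brute-force oracles; xi-cluster
extraction on the ordering reuses scikit-learn's extractor, and k-means and
UMAP are scikit-learn / umap-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans, cluster_optics_xi
from sklearn.metrics import adjusted_rand_score

from .cysclass import CysteineFramework, map_cysteine_framework

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}


class EmbedError(ValueError):
    pass


@dataclass(frozen=True)
class ProjectionParams:
    """UMAP parameters; the defaults are the study settings."""

    n_neighbors: int = 25
    min_dist: float = 0.5
    n_components: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise EmbedError("n_neighbors must be >= 2")
        if not (0 <= self.min_dist < 1):
            raise EmbedError("min_dist must be in [0, 1)")


@dataclass(frozen=True)
class ClusteringParams:
    kmeans_k: int = 7
    dbscan_eps: float = 0.55
    dbscan_min_pts: int = 5
    optics_xi: float = 0.01
    optics_min_pts: int = 5     # reuses the DBSCAN value; not fixed by the study
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmeans_k < 1 or self.dbscan_min_pts < 1:
            raise EmbedError("k and min_pts must be >= 1")
        if self.dbscan_eps <= 0 or not (0 < self.optics_xi < 1):
            raise EmbedError("eps must be > 0 and xi in (0,1)")


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def composition20(sequence: str) -> np.ndarray:
    """Amino-acid composition over the 20 standard residues (sums to 1);
    non-standard residues are dropped from numerator and denominator."""
    counts = np.zeros(20)
    for a in sequence:
        i = _AA_INDEX.get(a)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise EmbedError("sequence has no standard residues")
    return counts / total


def kmer2(sequence: str) -> np.ndarray:
    """Normalized 2-mer counts (400D)."""
    counts = np.zeros(400)
    for a, b in zip(sequence, sequence[1:]):
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is not None and ib is not None:
            counts[ia * 20 + ib] += 1
    total = counts.sum()
    return counts / total if total else counts


def cys_descriptor(sequence: str,
                   framework: CysteineFramework | None = None) -> np.ndarray:
    """16D framework descriptor: 10 slot-occupancy flags, extra-cysteine
    count, loop-II extras, loop-II extension, tail length, core length and
    mature length."""
    fw = framework if framework is not None else map_cysteine_framework(sequence)
    return np.array([
        *[float(o) for o in fw.slot_occupancy],
        float(len(fw.extra_cys)), float(fw.extra_cys_loop2),
        float(fw.loop2_extension), float(fw.tail_length),
        float(fw.core_end), float(len(sequence)),
    ])


_MODES = {"composition20", "kmer", "cys_descriptor", "imported"}


def compose_features(sequences: dict | Sequence, mode: str,
                     imported: tuple | None = None,
                     frameworks: dict | None = None
                     ) -> tuple[list[str], np.ndarray]:
    """Build one feature matrix; rows follow input order.

    `sequences` is a mapping id->mature sequence (or records with .id and
    .sequence). `imported` is an (ids, matrix) pair joined by id.
    """
    if mode not in _MODES:
        raise EmbedError(f"unknown feature mode {mode!r}")
    if hasattr(sequences, "items"):
        pairs = list(sequences.items())
    else:
        pairs = [(r.id, r.sequence) for r in sequences]
    ids = [i for i, _ in pairs]
    if mode == "imported":
        if imported is None:
            raise EmbedError("imported mode needs an (ids, matrix) pair")
        imp_ids, matrix = imported
        index = {pid: k for k, pid in enumerate(imp_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise EmbedError(f"imported vectors missing ids: {missing}")
        return ids, matrix[[index[i] for i in ids]]
    rows = []
    for pid, seq in pairs:
        if not seq:
            raise EmbedError(f"empty sequence for {pid}")
        if mode == "composition20":
            rows.append(composition20(seq))
        elif mode == "kmer":
            rows.append(kmer2(seq))
        else:
            fw = frameworks.get(pid) if frameworks else None
            rows.append(cys_descriptor(seq, fw))
    return ids, np.vstack(rows)


def stack_features(*matrices: np.ndarray) -> np.ndarray:
    """Concatenate feature blocks column-wise."""
    return np.hstack(matrices)


def zscore(matrix: np.ndarray) -> np.ndarray:
    """Per-dimension standardization; constant dimensions map to 0."""
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    sd[sd == 0] = 1.0
    return (matrix - mu) / sd


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project(features: np.ndarray,
            params: ProjectionParams | None = None) -> np.ndarray:
    """UMAP projection; deterministic for fixed seed and input order."""
    import umap  # deferred: numba compilation is slow at import time

    params = params or ProjectionParams()
    n = features.shape[0]
    if n < params.n_neighbors + 1:
        raise EmbedError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} points "
            f"(got {n}); lower n_neighbors")
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors, min_dist=params.min_dist,
        n_components=params.n_components, random_state=params.seed)
    coords = reducer.fit_transform(features)
    logger.info("projected %d points to %dD (n_neighbors=%d, min_dist=%.2f)",
                n, params.n_components, params.n_neighbors, params.min_dist)
    return np.asarray(coords, dtype=float)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def kmeans(points: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means++ / Lloyd to convergence (tol 1e-6, max 300 iterations)."""
    n = points.shape[0]
    if n < k:
        raise EmbedError(f"k-means needs n >= k (n={n}, k={k})")
    model = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                   tol=1e-6, random_state=seed, algorithm="lloyd")
    return model.fit_predict(points)


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Density-based clustering; noise labeled -1.

    A point is core iff >= min_pts points (self included) lie within
    Euclidean eps. Clusters are connected components of the
    mutually-reachable core points, numbered 0,1,... in order of their
    lowest point index; border points join the lowest-indexed neighbouring
    cluster; unreachable points are noise.
    """
    if eps <= 0:
        raise EmbedError("eps must be > 0")
    n = points.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    dist = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))
    neighbor = dist <= eps
    core = neighbor.sum(axis=1) >= min_pts

    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # BFS over density-connected core points
        stack = [i]
        labels[i] = cluster
        while stack:
            p = stack.pop()
            for q in np.flatnonzero(neighbor[p]):
                if core[q] and labels[q] == -1:
                    labels[q] = cluster
                    stack.append(q)
        cluster += 1
    # border assignment: lowest cluster index among core neighbours
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        neigh = [labels[q] for q in np.flatnonzero(neighbor[i])
                 if core[q] and labels[q] != -1]
        if neigh:
            labels[i] = min(neigh)
    return labels


@dataclass(frozen=True)
class OpticsResult:
    ordering: np.ndarray
    reachability: np.ndarray
    core_distances: np.ndarray
    predecessor: np.ndarray
    labels: np.ndarray
    clusters: np.ndarray          # (k, 2) ordering-index ranges of the tree


def optics_order(points: np.ndarray, min_pts: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OPTICS reachability ordering (max_eps = infinity).

    Deterministic: each sweep starts at the lowest-index unprocessed point
    and the next point is the unprocessed one with minimal reachability,
    ties to the lowest index.
    """
    n = points.shape[0]
    if n < min_pts:
        raise EmbedError(f"OPTICS needs n >= min_pts (n={n}, min_pts={min_pts})")
    dist = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))
    core_dist = np.sort(dist, axis=1)[:, min_pts - 1]

    reach = np.full(n, np.inf)
    predecessor = np.full(n, -1, dtype=int)
    processed = np.zeros(n, dtype=bool)
    ordering = []
    for _ in range(n):
        unproc = np.flatnonzero(~processed)
        p = unproc[np.argmin(reach[unproc])]
        processed[p] = True
        ordering.append(p)
        new_reach = np.maximum(core_dist[p], dist[p])
        improved = (~processed) & (new_reach < reach)
        predecessor[improved] = p
        reach[improved] = new_reach[improved]
    return np.array(ordering), reach, core_dist, predecessor


def optics_xi(points: np.ndarray, min_pts: int = 5, xi: float = 0.01
              ) -> OpticsResult:
    """Reachability ordering followed by xi-cluster extraction; returns the
    leaf-level flat labels plus the cluster tree (ordering-index ranges)."""
    ordering, reach, core_dist, predecessor = optics_order(points, min_pts)
    with np.errstate(divide="ignore", invalid="ignore"):
        labels, clusters = cluster_optics_xi(
            reachability=reach, predecessor=predecessor, ordering=ordering,
            min_samples=min_pts, min_cluster_size=min_pts, xi=xi)
    return OpticsResult(ordering, reach, core_dist, predecessor,
                        labels, clusters)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index; noise labels are treated as a regular class."""
    if len(labels_a) != len(labels_b):
        raise EmbedError(
            f"label length mismatch: {len(labels_a)} vs {len(labels_b)}")
    if len(labels_a) < 2:
        raise EmbedError("need at least 2 points")
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def nearest_neighbor_purity(coords: np.ndarray, labels: Sequence) -> float:
    """Fraction of points whose nearest neighbour shares their label."""
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    nn = dist.argmin(axis=1)
    labels = np.asarray(labels)
    return float((labels[nn] == labels).mean())
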