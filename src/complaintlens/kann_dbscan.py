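"""Adaptive-parameter DBSCAN (KANN-DBSCAN).

DBSCAN needs a neighborhood radius ε and a density threshold Pmin; both
are notoriously hard to pick by hand.  The K-average-nearest-neighbor
(KANN) procedure derives them from the data:

1. Build the n×n distance matrix D and sort every row ascending; column
   k of the sorted matrix is the k-th-nearest-neighbor distance vector.
2. The mean of column k, D̄_k, is the ε candidate for that k.
3. For each candidate ε, Pmin is the expected ε-neighborhood size
   (1/n)·Σᵢ |{j : D(i,j) ≤ ε}|, counting the point itself.
4. Run DBSCAN for k = 1, 2, … and record the cluster count C_k.  When
   C_k stays constant over a window of consecutive k (default 3) the
   count N is considered stable; scanning continues while C_k = N, and
   the largest such k before the first deviation is the optimal k*.

Conventions fixed here: ε-neighborhoods include the point itself
(classical MinPts counting); Pmin stays real-valued (the expectation is
generally fractional) with the core test ``count ≥ Pmin``; border points
join the cluster of the lowest-index core point within ε, which makes
the labeling deterministic and order-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import ConfigError, InputError, NoStableClusteringError

NOISE = -1

_METRICS = ("euclidean", "cosine")


# ---------------------------------------------------------------------------
# distances and profiles
# ---------------------------------------------------------------------------

def pairwise_distances(points: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric n×n distance matrix with zero diagonal."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise InputError("pairwise_distances: need a 2-D array with n >= 2 rows")
    if not np.isfinite(points).all():
        raise InputError("pairwise_distances: non-finite input values")
    if metric not in _METRICS:
        raise ConfigError(f"unknown metric {metric!r}; one of {_METRICS}")
    d = cdist(points, points, metric=metric)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp round-off
    np.fill_diagonal(d, 0.0)
    return d


def validate_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.isfinite(d).all():
        raise InputError("distance matrix has non-finite entries")
    if not np.allclose(d, d.T):
        raise InputError("distance matrix must be symmetric")
    if np.abs(np.diag(d)).max() > 0:
        raise InputError("distance matrix must have a zero diagonal")
    if d.min() < 0:
        raise InputError("distance matrix must be non-negative")
    return d


def kdistance_profile(d: np.ndarray) -> np.ndarray:
    """Each row of the distance matrix sorted ascending.

    Column 0 is the all-zero self-distance vector; column k holds every
    object's k-th-nearest-neighbor distance.
    """
    d = validate_distance_matrix(d)
    return np.sort(d, axis=1)


def eps_candidates(profile: np.ndarray) -> np.ndarray:
    """ε candidate list D̄_k = column means of the sorted profile.

    Entry k is the K-mean nearest-neighbor distance for neighbor rank k;
    entry 0 is 0 and the vector is non-decreasing. Usable ranks run
    1..n−1 (there is no n-th neighbor distinct from the point itself).
    """
    return np.asarray(profile, dtype=float).mean(axis=0)


def pmin_expectation(d: np.ndarray, eps: float) -> float:
    """Expected ε-neighborhood size (1/n)·Σᵢ Pᵢ, self included."""
    if eps < 0:
        raise ConfigError(f"eps must be >= 0, got {eps}")
    d = np.asarray(d, dtype=float)
    return float((d <= eps).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# DBSCAN on a precomputed distance matrix
# ---------------------------------------------------------------------------

def dbscan(d: np.ndarray, eps: float, pmin: float) -> np.ndarray:
    """Density-based clustering from a distance matrix.

    Point i is core iff its ε-neighborhood (self included) holds at least
    ``pmin`` points.  Clusters are the connected components of the graph
    on core points with edges between core pairs within ε; components are
    numbered 0..N−1 by their smallest member index.  A non-core point
    within ε of a core point becomes a border point of the lowest-index
    such core's cluster; everything else is noise (−1).
    """
    if eps < 0:
        raise ConfigError(f"eps must be >= 0, got {eps}")
    if pmin < 1:
        raise ConfigError(f"pmin must be >= 1, got {pmin}")
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    within = d <= eps
    counts = within.sum(axis=1)
    core = counts >= pmin
    labels = np.full(n, NOISE, dtype=int)

    core_idx = np.nonzero(core)[0]
    if core_idx.size == 0:
        return labels

    adjacency = csr_matrix(within[np.ix_(core_idx, core_idx)])
    n_comp, comp = connected_components(adjacency, directed=False)
    # renumber components by smallest member index for gap-free stable ids
    remap = np.empty(n_comp, dtype=int)
    next_id = 0
    seen: set[int] = set()
    for c in comp:
        if c not in seen:
            seen.add(c)
            remap[c] = next_id
            next_id += 1
    labels[core_idx] = remap[comp]

    # border points: lowest-index core neighbor decides the cluster
    for i in np.nonzero(~core)[0]:
        neighbors = core_idx[within[i, core_idx]]
        if neighbors.size:
            labels[i] = labels[neighbors[0]]
    return labels


def n_clusters(labels: np.ndarray) -> int:
    return int(len(set(labels.tolist()) - {NOISE}))


# ---------------------------------------------------------------------------
# adaptive parameter selection
# ---------------------------------------------------------------------------

@dataclass
class TraceEntry:
    k: int
    eps: float
    pmin: float
    n_clusters: int


@dataclass
class ClusterSolution:
    k: int
    eps: float
    pmin: float
    labels: np.ndarray
    n_clusters: int
    trace: list[TraceEntry] = field(default_factory=list)


def select_parameters(
    d: np.ndarray,
    k_range: tuple[int, int] | None = None,
    stability_window: int = 3,
) -> ClusterSolution:
    """Stability-driven search for (k*, ε*, Pmin*).

    For each k in the (inclusive) range, ε_k = D̄_k and Pmin_k is the
    ε_k-neighborhood expectation; DBSCAN's cluster count C_k is recorded.
    The stable count N is the value of the first run of
    ``stability_window`` consecutive equal C_k; scanning continues while
    C_k = N and k* is the largest such k before the first deviation (or
    the end of the range).

    Raises :class:`NoStableClusteringError` (carrying the full trace) if
    no such run exists.
    """
    d = validate_distance_matrix(d)
    n = d.shape[0]
    if k_range is None:
        k_range = (1, min(n - 1, 60))
    k_min, k_max = k_range
    if not (1 <= k_min <= k_max <= n - 1):
        raise ConfigError(
            f"k_range {k_range} outside 1..{n - 1} for n = {n} objects"
        )
    if stability_window < 2:
        raise ConfigError(f"stability_window must be >= 2, got {stability_window}")

    candidates = eps_candidates(kdistance_profile(d))
    trace: list[TraceEntry] = []
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        eps_k = float(candidates[k])
        pmin_k = pmin_expectation(d, eps_k)
        labels = dbscan(d, eps_k, max(pmin_k, 1.0))
        labels_by_k[k] = labels
        trace.append(TraceEntry(k=k, eps=eps_k, pmin=pmin_k,
                                n_clusters=n_clusters(labels)))

    counts = [t.n_clusters for t in trace]
    stable_start = None
    for i in range(len(counts) - stability_window + 1):
        window = counts[i : i + stability_window]
        if len(set(window)) == 1:
            stable_start = i
            break
    if stable_start is None:
        raise NoStableClusteringError(
            f"no run of {stability_window} consecutive equal cluster counts "
            f"in k range {k_min}..{k_max}",
            trace,
        )
    stable_n = counts[stable_start]
    last = stable_start + stability_window - 1
    while last + 1 < len(counts) and counts[last + 1] == stable_n:
        last += 1
    best = trace[last]
    return ClusterSolution(
        k=best.k,
        eps=best.eps,
        pmin=best.pmin,
        labels=labels_by_k[best.k],
        n_clusters=best.n_clusters,
        trace=trace,
    )


def solve_fixed(
    d: np.ndarray,
    k: int | None = None,
    eps: float | None = None,
    pmin: float | None = None,
) -> ClusterSolution:
    """Fixed-parameter mode that skips the stability search.

    Supply ε directly, or a neighbor rank k from which ε = D̄_k is taken;
    Pmin defaults to the ε-neighborhood expectation.
    """
    d = validate_distance_matrix(d)
    if eps is None:
        if k is None:
            raise ConfigError("solve_fixed: provide k and/or eps")
        if not 1 <= k <= d.shape[0] - 1:
            raise ConfigError(f"k={k} outside 1..{d.shape[0] - 1}")
        eps = float(eps_candidates(kdistance_profile(d))[k])
    if pmin is None:
        pmin = pmin_expectation(d, eps)
    labels = dbscan(d, eps, max(pmin, 1.0))
    entry = TraceEntry(k=k if k is not None else 0, eps=eps, pmin=pmin,
                       n_clusters=n_clusters(labels))
    return ClusterSolution(
        k=entry.k, eps=eps, pmin=pmin, labels=labels,
        n_clusters=entry.n_clusters, trace=[entry],
    )
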