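"""Connectivity-state clustering: L1 (Manhattan) K-means over pooled windows.

Windows from all subjects are pooled, each vectorized as the strict upper
triangle of its Fisher-z connectivity matrix, and partitioned into recurring
connectivity states by K-means under the Manhattan distance. The centroid
update is the coordinate-wise median of the assigned rows — the L1-optimal
center — so every iteration is a descent step for the L1 objective
(mean-update K-means with L1 assignment is not). The number of states is
chosen by the elbow criterion, read as the maximal discrete second
difference of the cost-vs-K curve.

States are relabeled so that state 1 is the strongest-connected (largest
mean absolute centroid value), matching the strong / sparse / intermediate
ordering conventional in dynamic-connectivity reports.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringError",
    "WindowFeatureMatrix",
    "StatePartition",
    "ElbowCurve",
    "vectorize_fc",
    "devectorize_fc",
    "build_feature_matrix",
    "kmeans_manhattan",
    "select_k_elbow",
    "validate_states",
    "rank_states_by_strength",
    "match_state_labels",
    "state_recovery_accuracy",
]

_SYMMETRY_TOL = 1e-10

try:  # optional compiled kernel; cdist fallback keeps results identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class ClusteringError(ValueError):
    """Invalid clustering input or configuration."""


# ---------------------------------------------------------------------------
# feature vectorization
# ---------------------------------------------------------------------------

def vectorize_fc(z_matrix: np.ndarray) -> np.ndarray:
    """Row-major strict upper triangle of a symmetric matrix (length N(N-1)/2)."""
    z = np.asarray(z_matrix)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ClusteringError("expected a square matrix")
    if not np.allclose(z, z.T, atol=_SYMMETRY_TOL):
        raise ClusteringError("matrix is asymmetric beyond 1e-10")
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu]


def devectorize_fc(vector: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`: rebuild the symmetric N x N matrix."""
    vector = np.asarray(vector)
    if vector.size != n * (n - 1) // 2:
        raise ClusteringError("vector length does not match N(N-1)/2")
    m = np.full((n, n), float(diagonal))
    iu = np.triu_indices(n, k=1)
    m[iu] = vector
    m[(iu[1], iu[0])] = vector
    return m


@dataclass
class WindowFeatureMatrix:
    """Pooled (subject, window) x edge-feature matrix for clustering."""

    X: np.ndarray
    row_index: list[tuple[str, int]]
    n_rois: int

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.row_index):
            raise ClusteringError("row_index length must match the feature matrix")
        if not np.all(np.isfinite(self.X)):
            raise ClusteringError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def build_feature_matrix(z_series_list: Sequence, dtype=np.float32) -> WindowFeatureMatrix:
    """Stack all subjects' vectorized z-windows into one feature matrix.

    Features are held in single precision by default: z values are O(1) and
    the L1 objective only compares sums of ~1e3 absolute differences, for
    which float32 is ample while halving memory traffic.
    """
    blocks, index = [], []
    n_rois = None
    for zs in z_series_list:
        w, n, _ = zs.z.shape
        if n_rois is None:
            n_rois = n
        elif n != n_rois:
            raise ClusteringError("subjects disagree on ROI count")
        iu = np.triu_indices(n, k=1)
        blocks.append(zs.z[:, iu[0], iu[1]].astype(dtype))
        index.extend((zs.subject_id, wi) for wi in range(w))
    return WindowFeatureMatrix(X=np.vstack(blocks), row_index=index, n_rois=int(n_rois))


# ---------------------------------------------------------------------------
# L1 K-means core
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _assign_l1_nb(x, c):  # pragma: no cover - exercised via wrapper
        n, d = x.shape
        k = c.shape[0]
        labels = np.empty(n, dtype=np.int64)
        dists = np.empty(n, dtype=np.float64)
        d4 = d - (d % 4)
        for i in range(n):
            best = np.inf
            bj = 0
            for j in range(k):
                # four independent accumulators keep the reduction
                # vectorizable instead of one serial dependency chain
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                s3 = 0.0
                for l in range(0, d4, 4):
                    s0 += abs(x[i, l] - c[j, l])
                    s1 += abs(x[i, l + 1] - c[j, l + 1])
                    s2 += abs(x[i, l + 2] - c[j, l + 2])
                    s3 += abs(x[i, l + 3] - c[j, l + 3])
                s = s0 + s1 + s2 + s3
                for l in range(d4, d):
                    s += abs(x[i, l] - c[j, l])
                if s < best:
                    best = s
                    bj = j
            labels[i] = bj
            dists[i] = best
        return labels, dists


def _assign_l1(x: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each row to its L1-nearest centroid; ties go to the lowest index."""
    if _HAVE_NUMBA and x.shape[0] * x.shape[1] > 20_000:
        return _assign_l1_nb(np.ascontiguousarray(x), np.ascontiguousarray(c))
    d = cdist(x, c, metric="cityblock")
    labels = np.argmin(d, axis=1)
    return labels, d[np.arange(x.shape[0]), labels]


def _init_plusplus(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """K-means++-style seeding under the L1 distance."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]), dtype=x.dtype)
    centers[0] = x[rng.integers(n)]
    d = cdist(x, centers[:1], metric="cityblock")[:, 0]
    for j in range(1, k):
        total = d.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d / total)
        centers[j] = x[idx]
        d = np.minimum(d, cdist(x, centers[j : j + 1], metric="cityblock")[:, 0])
    return centers


def _fit_once(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    centers = _init_plusplus(x, k, rng)
    labels = np.full(x.shape[0], -1, dtype=np.int64)
    cost_history: list[float] = []
    for _ in range(max_iter):
        new_labels, dists = _assign_l1(x, centers)
        # an empty cluster is reseeded from (and claims) the point currently
        # farthest from its assigned centroid; claimed points are excluded
        # from later claims so every empty cluster ends up non-empty
        counts = np.bincount(new_labels, minlength=k)
        for empty in np.flatnonzero(counts == 0):
            far = int(np.argmax(dists))
            logger.info("reseeding empty cluster %d from row %d", empty, far)
            centers[empty] = x[far]
            new_labels[far] = empty
            dists[far] = -np.inf
        if (counts == 0).any():
            dists = np.maximum(dists, 0.0)
            counts = np.bincount(new_labels, minlength=k)
        cost_history.append(float(dists.sum()))
        if np.array_equal(new_labels, labels):
            break
        # only clusters whose membership changed need a fresh median
        if labels[0] < 0:
            changed = range(k)
        else:
            moved = new_labels != labels
            changed = np.union1d(labels[moved], new_labels[moved])
        labels = new_labels
        for j in changed:
            centers[j] = np.median(x[labels == j], axis=0)
    return labels, centers, cost_history[-1], cost_history


@dataclass
class StatePartition:
    """Fitted connectivity-state partition (labels are 1-based)."""

    n_states: int
    centroids: np.ndarray  # K x N(N-1)/2
    labels: np.ndarray  # 1..K per pooled window
    total_cost: float
    row_index: list[tuple[str, int]] = field(default_factory=list)
    state_order: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cost_history: list[float] = field(default_factory=list)

    def state_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_states + 1)[1:]


def kmeans_manhattan(
    features: WindowFeatureMatrix | np.ndarray,
    k: int,
    n_init: int = 20,
    max_iter: int = 300,
    seed: int | np.random.SeedSequence | None = 0,
    rank: bool = True,
) -> StatePartition:
    """Best-of-``n_init`` L1 K-means with coordinate-wise-median updates.

    Runs ``n_init`` independent seeded restarts to exact label convergence
    (or ``max_iter``) and keeps the restart with the lowest total Manhattan
    cost. With ``rank=True`` (default) states are renumbered by descending
    mean absolute centroid connectivity, so state 1 is the strongest state.
    """
    if isinstance(features, WindowFeatureMatrix):
        x, row_index = features.X, features.row_index
    else:
        x = np.asarray(features)
        row_index = []
    if k < 1 or k > x.shape[0]:
        raise ClusteringError("k must satisfy 1 <= k <= number of rows")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best: Optional[tuple] = None
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        labels, centers, cost, history = _fit_once(x, k, rng, max_iter)
        if best is None or cost < best[2]:
            best = (labels, centers, cost, history)
    labels, centers, cost, history = best
    part = StatePartition(
        n_states=k,
        centroids=np.asarray(centers, dtype=np.float64),
        labels=labels + 1,
        total_cost=cost,
        row_index=list(row_index),
        state_order=np.arange(k),
        cost_history=history,
    )
    return rank_states_by_strength(part) if rank else part


def rank_states_by_strength(partition: StatePartition) -> StatePartition:
    """Renumber states by descending mean |centroid| (ties: original index)."""
    strength = np.abs(partition.centroids).mean(axis=1)
    order = np.lexsort((np.arange(partition.n_states), -strength))
    remap = np.empty(partition.n_states, dtype=np.int64)
    remap[order] = np.arange(partition.n_states)
    return StatePartition(
        n_states=partition.n_states,
        centroids=partition.centroids[order],
        labels=remap[partition.labels - 1] + 1,
        total_cost=partition.total_cost,
        row_index=list(partition.row_index),
        state_order=order,
        cost_history=list(partition.cost_history),
    )


@dataclass
class ElbowCurve:
    """Cost-vs-K curve with the elbow-selected number of states."""

    k_values: np.ndarray
    costs: np.ndarray
    selected_k: int
    partitions: dict[int, StatePartition] = field(default_factory=dict)


def select_k_elbow(
    features: WindowFeatureMatrix | np.ndarray,
    k_range: Sequence[int] = range(2, 9),
    n_init: int = 20,
    max_iter: int = 300,
    seed: int | np.random.SeedSequence | None = 0,
    keep_partitions: bool = False,
    method: str = "second_difference",
) -> ElbowCurve:
    """Elbow model selection: maximal second difference of the cost curve.

    ``selected_k`` is the interior candidate maximizing
    ``cost(k-1) - 2*cost(k) + cost(k+1)`` (or the distortion ratio when
    ``method="distortion_ratio"``); exact ties resolve to the lowest k.
    The full curve is returned for audit.
    """
    k_values = np.asarray(list(k_range), dtype=int)
    if k_values.size < 3:
        raise ClusteringError("elbow selection needs at least 3 candidate k values")
    if np.any(np.diff(k_values) <= 0):
        raise ClusteringError("k_range must be strictly increasing")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(k_values.size)
    costs = np.empty(k_values.size)
    partitions: dict[int, StatePartition] = {}
    for i, k in enumerate(k_values):
        part = kmeans_manhattan(
            features, int(k), n_init=n_init, max_iter=max_iter, seed=children[i]
        )
        costs[i] = part.total_cost
        if keep_partitions:
            partitions[int(k)] = part
    selected_k = elbow_from_curve(k_values, costs, method=method)
    if keep_partitions:
        partitions = {selected_k: partitions[selected_k]}
    return ElbowCurve(
        k_values=k_values, costs=costs, selected_k=selected_k, partitions=partitions
    )


def elbow_from_curve(
    k_values: np.ndarray, costs: np.ndarray, method: str = "second_difference"
) -> int:
    """Elbow of a cost-vs-K curve at an interior candidate.

    ``second_difference`` (default) maximizes the discrete curvature
    ``cost(k-1) - 2 cost(k) + cost(k+1)``; ``distortion_ratio`` maximizes
    the ratio of the drop into k over the drop out of k,
    ``(cost(k-1) - cost(k)) / (cost(k) - cost(k+1))``. Ties resolve to the
    lowest k in both readings.
    """
    k_values = np.asarray(k_values)
    costs = np.asarray(costs, dtype=float)
    if k_values.size < 3:
        raise ClusteringError("need at least 3 points for an elbow")
    if method == "second_difference":
        score = costs[:-2] - 2.0 * costs[1:-1] + costs[2:]
    elif method == "distortion_ratio":
        drop_in = costs[:-2] - costs[1:-1]
        drop_out = costs[1:-1] - costs[2:]
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(drop_out > 0, drop_in / drop_out, np.inf)
    else:
        raise ClusteringError(f"unknown elbow method {method!r}")
    best = int(np.argmax(score))  # argmax takes the first (lowest k) on ties
    return int(k_values[1 + best])


def validate_states(partition: StatePartition, min_windows: int = 10) -> dict[int, bool]:
    """State validity: each state must hold at least ``min_windows`` pooled windows."""
    counts = partition.state_counts()
    result = {s + 1: bool(counts[s] >= min_windows) for s in range(partition.n_states)}
    for s, ok in result.items():
        if not ok:
            logger.warning(
                "state %d holds only %d windows (< %d)", s, counts[s - 1], min_windows
            )
    return result


# ---------------------------------------------------------------------------
# ground-truth comparison helpers
# ---------------------------------------------------------------------------

def match_state_labels(
    predicted: np.ndarray, truth: np.ndarray, k: int
) -> np.ndarray:
    """Optimal 1..K relabeling of ``predicted`` onto ``truth`` (Hungarian)."""
    confusion = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(predicted, truth):
        confusion[p - 1, t - 1] += 1
    rows, cols = linear_sum_assignment(-confusion)
    mapping = np.empty(k, dtype=np.int64)
    mapping[rows] = cols
    return mapping[predicted - 1] + 1


def state_recovery_accuracy(predicted: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Fraction of windows correct after optimal state matching."""
    remapped = match_state_labels(np.asarray(predicted), np.asarray(truth), k)
    return float(np.mean(remapped == np.asarray(truth)))
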