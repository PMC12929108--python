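"""Sparsity-thresholded binary graph metrics for state-wise brain networks.

A subject's network in a state is the entrywise mean of the Fisher-z
connectivity matrices of the windows assigned to that state. Each weighted
network is binarized over a sparsity sweep (default 0.10-0.40, step 0.01) by
retaining the largest signed edge weights, and global (global efficiency GE,
local efficiency LE, small-worldness sigma) and nodal (local efficiency Ne,
clustering Ncc, degree Dc, betweenness Bc) metrics are computed per level.
Sweep-level values are aggregated by the trapezoidal area under the
metric-vs-sparsity curve (AUC).

Shortest-path primitives are breadth-first (unweighted); betweenness is
unnormalized and counts each unordered node pair once.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "GraphInputError",
    "StateNetwork",
    "BinaryGraph",
    "SmallWorldResult",
    "default_sparsity_sweep",
    "state_network",
    "threshold_by_sparsity",
    "all_pairs_distances",
    "global_efficiency",
    "nodal_degree",
    "nodal_clustering",
    "nodal_local_efficiency",
    "local_efficiency",
    "betweenness",
    "small_worldness",
    "metric_auc",
    "sweep_metrics",
]


class GraphInputError(ValueError):
    """Invalid graph-analysis input."""


def default_sparsity_sweep(
    low: float = 0.10, high: float = 0.40, step: float = 0.01
) -> np.ndarray:
    """The default 31-level sparsity sweep 0.10, 0.11, ..., 0.40."""
    n_levels = int(round((high - low) / step)) + 1
    if not np.isclose(low + (n_levels - 1) * step, high, atol=1e-9):
        raise GraphInputError("sweep step must divide the range evenly")
    return np.round(low + step * np.arange(n_levels), 10)


@dataclass
class StateNetwork:
    """Subject's mean z-connectivity over the windows spent in one state."""

    subject_id: str
    state: int
    mean_z_matrix: np.ndarray
    n_windows_used: int


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphInputError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise GraphInputError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise GraphInputError("adjacency must have a zero diagonal")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


def state_network(z_series, timeline, state: int) -> Optional[StateNetwork]:
    """Mean z-matrix over the subject's windows assigned to ``state``.

    Returns ``None`` (an absent-network sentinel, logged) when the subject
    never visits the state; such subjects drop out of that state's group
    comparisons.
    """
    mask = np.asarray(timeline.labels) == state
    if not mask.any():
        logger.info("subject %s never visits state %d", z_series.subject_id, state)
        return None
    mean = z_series.z[mask].mean(axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    return StateNetwork(
        subject_id=z_series.subject_id,
        state=state,
        mean_z_matrix=mean,
        n_windows_used=int(mask.sum()),
    )


def threshold_by_sparsity(
    weighted: np.ndarray, sparsity: float, use_absolute: bool = False
) -> BinaryGraph:
    """Binarize by keeping the ``floor(sparsity * N(N-1)/2)`` largest edges.

    Edges are ranked by signed weight (descending) by default, which
    effectively excludes negative edges at conventional sparsities;
    ``use_absolute=True`` ranks by |weight| instead. Exact ties across the
    cutoff are broken deterministically by row-major edge index (ascending)
    and logged.
    """
    w = np.asarray(weighted, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise GraphInputError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise GraphInputError("weight matrix must be symmetric")
    if not 0.0 < sparsity < 1.0:
        raise GraphInputError("sparsity must lie in (0, 1)")
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.abs(w[iu]) if use_absolute else w[iu]
    m = vals.size
    k_edges = int(np.floor(sparsity * m))
    order = np.lexsort((np.arange(m), -vals))  # value desc, then index asc
    if 0 < k_edges < m and vals[order[k_edges - 1]] == vals[order[k_edges]]:
        logger.info(
            "tie at the sparsity cutoff (weight %.6g); row-major order applied",
            vals[order[k_edges - 1]],
        )
    keep = order[:k_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj += adj.T
    return BinaryGraph(adjacency=adj, sparsity=float(sparsity))


# ---------------------------------------------------------------------------
# metric primitives
# ---------------------------------------------------------------------------

def _adj(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    return graph.adjacency if isinstance(graph, BinaryGraph) else np.asarray(graph)


def all_pairs_distances(graph: BinaryGraph | np.ndarray) -> np.ndarray:
    """Breadth-first hop distances; ``inf`` for disconnected pairs."""
    a = _adj(graph)
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    d = shortest_path(csr_array(a.astype(np.int32)), method="D", unweighted=True)
    np.fill_diagonal(d, 0.0)
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(graph: BinaryGraph | np.ndarray) -> float:
    """Mean over ordered node pairs of 1/d(i, j), with 1/inf = 0."""
    return _efficiency_from_distances(all_pairs_distances(graph))


def nodal_degree(graph: BinaryGraph | np.ndarray, node: Optional[int] = None):
    """Degree centrality Dc: edge count per node."""
    deg = _adj(graph).sum(axis=1).astype(np.int64)
    return deg if node is None else int(deg[node])


def nodal_clustering(graph: BinaryGraph | np.ndarray, node: Optional[int] = None):
    """Clustering coefficient Ncc = 2*triangles / (k*(k-1)); 0 when k < 2."""
    a = _adj(graph)
    g = nx.from_numpy_array(a)
    cc = nx.clustering(g)
    out = np.array([cc[i] for i in range(a.shape[0])], dtype=float)
    return out if node is None else float(out[node])


def nodal_local_efficiency(graph: BinaryGraph | np.ndarray, node: Optional[int] = None):
    """Ne: global efficiency of the neighbor-induced subgraph (0 if < 2 neighbors)."""
    a = _adj(graph)
    if node is not None:
        nbrs = np.flatnonzero(a[node])
        if nbrs.size < 2:
            return 0.0
        return _efficiency_from_distances(all_pairs_distances(a[np.ix_(nbrs, nbrs)]))
    return np.array([nodal_local_efficiency(a, i) for i in range(a.shape[0])])


def local_efficiency(graph: BinaryGraph | np.ndarray) -> float:
    """LE: mean nodal local efficiency over all nodes."""
    ne = nodal_local_efficiency(graph)
    return float(np.mean(ne)) if ne.size else 0.0


def betweenness(
    graph: BinaryGraph | np.ndarray,
    node: Optional[int] = None,
    normalized: bool = False,
):
    """Shortest-path betweenness (each unordered pair once), unnormalized
    by default; ``normalized=True`` divides by (N-1)(N-2)/2.

    Endpoints are excluded; computed by Brandes dependency accumulation.
    """
    a = _adj(graph)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    out = np.array([bc[i] for i in range(a.shape[0])], dtype=float)
    return out if node is None else float(out[node])


@dataclass
class SmallWorldResult:
    gamma: float  # C / C_rand
    lam: float  # L / L_rand
    sigma: float  # gamma / lam
    component_coverage: float  # fraction of nodes in the analyzed component


def _characteristic_path_length(a: np.ndarray) -> float:
    """Mean finite off-diagonal hop distance on the largest component."""
    n_comp, membership = connected_components(csr_array(a.astype(np.int32)))
    largest = np.argmax(np.bincount(membership))
    nodes = np.flatnonzero(membership == largest)
    if nodes.size < 2:
        return 0.0
    d = all_pairs_distances(a[np.ix_(nodes, nodes)])
    iu = np.triu_indices(nodes.size, k=1)
    return float(d[iu].mean())


def small_worldness(
    graph: BinaryGraph | np.ndarray,
    n_null: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
) -> SmallWorldResult:
    """Small-world coefficients against degree-preserving rewired nulls.

    ``gamma`` is the mean clustering ratio, ``lam`` the characteristic path
    length ratio (mean finite distance on the largest connected component,
    whose node coverage is reported) and ``sigma = gamma / lam``. Nulls are
    Maslov-Sneppen double-edge swaps (10 x |E| accepted swaps per null); if
    rewiring is impossible (e.g. a complete graph) a density-matched random
    graph is used instead, which is logged.
    """
    a = _adj(graph)
    n_comp, membership = connected_components(csr_array(a.astype(np.int32)))
    largest = np.argmax(np.bincount(membership))
    nodes = np.flatnonzero(membership == largest)
    coverage = nodes.size / a.shape[0]
    if coverage < 1.0:
        logger.info("small-worldness computed on largest component (%.0f%% of nodes)",
                    100 * coverage)
    sub = a[np.ix_(nodes, nodes)]
    g = nx.from_numpy_array(sub)
    n_edges = g.number_of_edges()
    c_obs = nx.average_clustering(g) if g.number_of_nodes() > 0 else 0.0
    l_obs = _characteristic_path_length(sub)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    c_null, l_null = [], []
    for child in ss.spawn(n_null):
        rng = np.random.default_rng(child)
        h = g.copy()
        try:
            if n_edges >= 2 and g.number_of_nodes() >= 4:
                nx.double_edge_swap(
                    h, nswap=10 * n_edges, max_tries=1000 * n_edges + 100, seed=rng
                )
            else:
                raise nx.NetworkXError("graph too small to rewire")
        except nx.NetworkXException:
            logger.info("degree-preserving rewiring unavailable; density-matched null used")
            h = nx.gnm_random_graph(g.number_of_nodes(), n_edges, seed=rng)
        c_null.append(nx.average_clustering(h))
        l_null.append(_characteristic_path_length(nx.to_numpy_array(h)))
    c_rand = float(np.mean(c_null))
    l_rand = float(np.mean(l_null))
    gamma = c_obs / c_rand if c_rand > 0 else float("nan")
    lam = l_obs / l_rand if l_rand > 0 else float("nan")
    sigma = gamma / lam if lam and np.isfinite(lam) and lam > 0 else float("nan")
    return SmallWorldResult(gamma=gamma, lam=lam, sigma=sigma, component_coverage=coverage)


def metric_auc(sparsities: Sequence[float], values: np.ndarray) -> float | np.ndarray:
    """Trapezoidal area under a metric-vs-sparsity curve.

    ``values`` may be 1-D (global metric) or 2-D with one row per sparsity
    level (nodal metrics; the AUC is returned per column).
    """
    s = np.asarray(sparsities, dtype=float)
    v = np.asarray(values, dtype=float)
    if s.ndim != 1 or s.size < 2 or np.any(np.diff(s) <= 0):
        raise GraphInputError("sparsities must be increasing with at least 2 levels")
    if v.shape[0] != s.size:
        raise GraphInputError("one value row per sparsity level is required")
    return np.trapezoid(v, s, axis=0)


def sweep_metrics(
    weighted: np.ndarray,
    sparsities: Optional[Sequence[float]] = None,
    include_small_world: bool = False,
    n_null: int = 20,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global and nodal metrics of one weighted network over the sweep.

    Returns ``(global_df, nodal_df)``: one row per sparsity level
    (global), and one row per (sparsity, node) pair (nodal).
    """
    if sparsities is None:
        sparsities = default_sparsity_sweep()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sw_seeds = ss.spawn(len(list(sparsities)))
    global_rows, nodal_rows = [], []
    n = np.asarray(weighted).shape[0]
    for i, s in enumerate(sparsities):
        g = threshold_by_sparsity(weighted, float(s))
        row = {
            "sparsity": float(s),
            "GE": global_efficiency(g),
            "LE": local_efficiency(g),
        }
        if include_small_world:
            sw = small_worldness(g, n_null=n_null, seed=sw_seeds[i])
            row.update(
                {"gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma,
                 "component_coverage": sw.component_coverage}
            )
        global_rows.append(row)
        ncc = nodal_clustering(g)
        ne = nodal_local_efficiency(g)
        dc = nodal_degree(g)
        bc = betweenness(g)
        for node in range(n):
            nodal_rows.append(
                {
                    "sparsity": float(s),
                    "node": node,
                    "Ne": float(ne[node]),
                    "Ncc": float(ncc[node]),
                    "Dc": int(dc[node]),
                    "Bc": float(bc[node]),
                }
            )
    return pd.DataFrame(global_rows), pd.DataFrame(nodal_rows)
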