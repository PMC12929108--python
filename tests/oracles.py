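"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — matrix-power reachability, explicit
shortest-path enumeration, exhaustive threshold search — so the tested
implementations are checked against a second, structurally different route.
"""
from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# graph metrics (adjacency = symmetric 0/1 numpy array)
# ---------------------------------------------------------------------------

def bf_distances(a: np.ndarray) -> np.ndarray:
    """Hop distances via matrix powers: d(i,j) = min {k : (A^k)[i,j] > 0}."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    power = np.eye(n)
    for k in range(1, n):
        power = power @ a
        newly = (power > 0) & np.isinf(d)
        d[newly] = k
    return d

def bf_global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = bf_distances(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))

def bf_degree(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=1).astype(np.int64)

def bf_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        k = nbrs.size
        if k < 2:
            continue
        tri = 0
        for ii in range(k):
            for jj in range(ii + 1, k):
                tri += a[nbrs[ii], nbrs[jj]]
        out[v] = 2.0 * tri / (k * (k - 1))
    return out

def bf_nodal_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        if nbrs.size >= 2:
            out[v] = bf_global_efficiency(a[np.ix_(nbrs, nbrs)])
    return out

def bf_local_efficiency(a: np.ndarray) -> float:
    ne = bf_nodal_local_efficiency(a)
    return float(ne.mean()) if ne.size else 0.0

def _all_shortest_paths(a: np.ndarray, d: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Enumerate every shortest s-t path by walking the BFS distance field."""
    if not np.isfinite(d[s, t]):
        return []
    if s == t:
        return [[s]]
    paths = []
    for v in np.flatnonzero(a[s]):
        if d[v, t] == d[s, t] - 1:
            for tail in _all_shortest_paths(a, d, v, t):
                paths.append([s] + tail)
    return paths

def bf_betweenness(a: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    n = a.shape[0]
    d = bf_distances(a)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(a, d, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc

def bf_tree_betweenness_by_separation(a: np.ndarray) -> np.ndarray:
    """On a tree: Bc(v) = (#ordered pairs separated by removing v) / 2."""
    n = a.shape[0]
    bc = np.zeros(n)
    for v in range(n):
        sub = a.copy()
        sub[v, :] = 0
        sub[:, v] = 0
        d = bf_distances(sub)
        separated = 0
        for i in range(n):
            for j in range(n):
                if i != v and j != v and i != j and not np.isfinite(d[i, j]):
                    separated += 1
        bc[v] = separated / 2.0
    return bc


# ---------------------------------------------------------------------------
# temporal metrics
# ---------------------------------------------------------------------------

def rle_oracle(labels) -> list[tuple[int, int]]:
    """(value, run length) pairs via a plain left-to-right scan."""
    runs = []
    current, length = labels[0], 1
    for x in labels[1:]:
        if x == current:
            length += 1
        else:
            runs.append((int(current), length))
            current, length = x, 1
    runs.append((int(current), length))
    return runs

def mean_dwell_oracle(labels, k: int) -> np.ndarray:
    runs = rle_oracle(labels)
    out = np.zeros(k)
    for s in range(1, k + 1):
        lengths = [l for v, l in runs if v == s]
        if lengths:
            out[s - 1] = float(np.mean(lengths))
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def ols_residuals_oracle(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals via the normal equations solved explicitly."""
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    return y - x @ beta

def bh_oracle(p: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """BH by definition: search all thresholds; adjusted p = min_j>=i m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # largest i with p_(i) <= q*i/m rejects p_(1..i)
    cutoff = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= q * i / m:
            cutoff = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:cutoff]] = True
    adjusted_sorted = np.empty(m)
    for i in range(m):
        adjusted_sorted[i] = min(
            min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0
        )
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, reject

def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    return float(u @ v / np.sqrt((u @ u) * (v @ v)))

def partial_corr_recursive(x: np.ndarray, y: np.ndarray, covs: np.ndarray) -> float:
    """First-order recursion r_xy.z applied covariate by covariate."""
    covs = np.atleast_2d(np.asarray(covs, dtype=float).T).T
    variables = [np.asarray(x, float), np.asarray(y, float)] + [covs[:, j] for j in range(covs.shape[1])]
    n = len(variables)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = _pearson(variables[i], variables[j])

    def partial(i, j, controls):
        if not controls:
            return r[i, j]
        k = controls[-1]
        rest = controls[:-1]
        rij = partial(i, j, rest)
        rik = partial(i, k, rest)
        rjk = partial(j, k, rest)
        return (rij - rik * rjk) / np.sqrt((1 - rik**2) * (1 - rjk**2))

    return float(partial(0, 1, list(range(2, n))))

def chi2_oracle(table: np.ndarray) -> float:
    """Pearson chi-square statistic from the definition."""
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def two_pass_sd(values: np.ndarray) -> np.ndarray:
    """Sample SD over axis 0 via an explicit two-pass loop."""
    mean = values.mean(axis=0)
    acc = np.zeros_like(mean)
    for row in values:
        acc += (row - mean) ** 2
    return np.sqrt(acc / (values.shape[0] - 1))
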