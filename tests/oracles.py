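"""Independent brute-force graph-metric implementations.

Deliberately naive: explicit loops, Floyd-Warshall distances, recursive
geodesic enumeration for betweenness, closed-form regression sums.  Used
as oracles against the package's implementations; they share no code path
with trtnet.metrics.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def lengths_from_adjacency(adj: np.ndarray, weighted: bool) -> np.ndarray:
    n = adj.shape[0]
    lengths = np.full((n, n), INF)
    for i in range(n):
        lengths[i, i] = 0.0
        for j in range(n):
            if adj[i, j] > 0:
                lengths[i, j] = (1.0 / adj[i, j]) if weighted else 1.0
    return lengths


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    d = lengths.copy()
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_degree(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    return np.array([sum(adj[i, j] for j in range(n)) for i in range(n)])


def brute_global_efficiency(adj: np.ndarray, weighted: bool) -> float:
    d = floyd_warshall(lengths_from_adjacency(adj, weighted))
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_path_length(adj: np.ndarray, weighted: bool) -> float:
    d = floyd_warshall(lengths_from_adjacency(adj, weighted))
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    if all(np.isfinite(v) for v in vals):
        return float(np.mean(vals))
    inv = sum(1.0 / v for v in vals if np.isfinite(v) and v > 0)
    return n * (n - 1) / inv if inv > 0 else INF


def brute_nodal_efficiency(adj: np.ndarray, weighted: bool) -> np.ndarray:
    d = floyd_warshall(lengths_from_adjacency(adj, weighted))
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def brute_clustering(adj: np.ndarray, weighted: bool) -> np.ndarray:
    n = adj.shape[0]
    binary = (adj > 0).astype(float)
    wmax = adj.max() if adj.max() > 0 else 1.0
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if binary[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                if binary[j, h]:
                    if weighted:
                        s += (adj[i, j] / wmax * adj[i, h] / wmax
                              * adj[j, h] / wmax) ** (1.0 / 3.0)
                    else:
                        s += 1.0
        c[i] = 2.0 * s / (k * (k - 1))
    return c


def brute_local_efficiency(adj: np.ndarray, weighted: bool) -> float:
    n = adj.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals[i] = brute_global_efficiency(sub, weighted)
    return float(vals.mean())


def brute_betweenness(adj: np.ndarray, weighted: bool) -> np.ndarray:
    """Fractional betweenness via explicit geodesic enumeration.

    For every pair (s, t), recursively enumerates all shortest paths by
    only following edges that lie on some geodesic (checked against the
    Floyd-Warshall distances), then credits interior nodes 1/sigma_st
    per geodesic.
    """
    n = adj.shape[0]
    lengths = lengths_from_adjacency(adj, weighted)
    d = floyd_warshall(lengths)
    bc = np.zeros(n)
    tol = 1e-12

    def geodesics(u: int, t: int, visited: tuple) -> list[list[int]]:
        if u == t:
            return [[t]]
        out = []
        for v in range(n):
            if adj[u, v] > 0 and v not in visited:
                if abs(lengths[u, v] + d[v, t] - d[u, t]) <= tol * max(
                        1.0, abs(d[u, t])):
                    for tail in geodesics(v, t, visited + (v,)):
                        out.append([u] + tail)
        return out

    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]):
                continue
            paths = geodesics(s, t, (s,))
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def brute_assortativity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    k = brute_degree(adj)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] > 0:
                xs += [k[i], k[j]]
                ys += [k[j], k[i]]
    if len(xs) < 4:
        return float("nan")
    x, y = np.array(xs), np.array(ys)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def brute_hierarchy(adj: np.ndarray, weighted: bool) -> float:
    c = brute_clustering(adj, weighted)
    k = brute_degree(adj)
    kb = brute_degree((adj > 0).astype(float))
    idx = [i for i in range(adj.shape[0])
           if kb[i] >= 2 and c[i] > 0 and k[i] > 0]
    if len(idx) < 3:
        return float("nan")
    lk = np.log(k[idx])
    lc = np.log(c[idx])
    if lk.std() == 0:
        return float("nan")
    # closed-form least-squares slope
    slope = (((lk - lk.mean()) * (lc - lc.mean())).sum()
             / ((lk - lk.mean()) ** 2).sum())
    return float(-slope)


def brute_synchronization(adj: np.ndarray) -> float:
    n = adj.shape[0]
    lap = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                lap[i, i] = sum(adj[i, h] for h in range(n))
            else:
                lap[i, j] = -adj[i, j]
    ev = sorted(np.linalg.eigvalsh(lap))
    if ev[-1] <= 0 or ev[1] < 1e-10 * max(ev[-1], 1.0):
        return 0.0
    return float(ev[1] / ev[-1])


def brute_modularity_q(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman Q of a given partition, Q = sum_c (e_cc - a_c^2) with
    edge fractions computed from (possibly weighted) adjacency."""
    two_m = adj.sum()
    q = 0.0
    for mod in np.unique(labels):
        members = np.where(labels == mod)[0]
        e_cc = adj[np.ix_(members, members)].sum() / two_m
        a_c = adj[members, :].sum() / two_m
        q += e_cc - a_c ** 2
    return float(q)


def brute_participation(adj: np.ndarray,
                        labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = adj.shape[0]
    mods = np.unique(labels)
    pc = np.zeros(n)
    for i in range(n):
        k = sum(adj[i, j] for j in range(n))
        if k == 0:
            continue
        s = 0.0
        for mod in mods:
            kim = sum(adj[i, j] for j in range(n) if labels[j] == mod)
            s += (kim / k) ** 2
        pc[i] = 1.0 - s
    m = len(mods)
    pcnorm = (pc / (1.0 - 1.0 / m) if m > 1
              else np.full(n, float("nan")))
    return pc, pcnorm
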