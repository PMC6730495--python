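"""Independent brute-force oracles for graph measures.

Everything here is deliberately naive — BFS by hand, explicit path
enumeration, dense eigendecompositions — and shares no code with the
package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def bfs_distances(a: np.ndarray, source: int) -> np.ndarray:
    n = a.shape[0]
    dist = np.full(n, -1)
    dist[source] = 0
    queue = [source]
    while queue:
        u = queue.pop(0)
        for v in range(n):
            if a[u, v] and dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_pairs_distances(a: np.ndarray) -> np.ndarray:
    return np.stack([bfs_distances(a, s) for s in range(a.shape[0])])


def enumerate_shortest_paths(a: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """All shortest s-t paths by exhaustive DFS over the BFS layering."""
    dist = bfs_distances(a, s)
    if dist[t] < 0 or s == t:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in range(a.shape[0]):
            if a[u, v] and dist[v] == dist[u] + 1:
                extend(path + [v])

    extend([s])
    return paths


def betweenness_oracle(a: np.ndarray) -> np.ndarray:
    """Raw unordered-pair betweenness via full path enumeration."""
    n = a.shape[0]
    btw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = enumerate_shortest_paths(a, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            on_path = sum(1 for p in paths if v in p)
            btw[v] += on_path / len(paths)
    return btw


def clustering_oracle(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for u, v in itertools.combinations(nbrs, 2) if a[u, v]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def eigenvector_oracle(a: np.ndarray, iters: int = 20000) -> np.ndarray:
    """Dense power iteration on A + I (shift keeps convergence monotone)."""
    n = a.shape[0]
    v = np.ones(n) / np.sqrt(n)
    m = a.astype(float) + np.eye(n)
    for _ in range(iters):
        w = m @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            return v
        w /= nw
        if np.linalg.norm(w - v) < 1e-14:
            v = w
            break
        v = w
    return np.abs(v)


def subgraph_centrality_oracle(a: np.ndarray) -> np.ndarray:
    return np.diag(expm(a.astype(float))).copy()


def rich_club_oracle(a: np.ndarray, k: int) -> float:
    deg = a.sum(axis=0)
    members = [i for i in range(a.shape[0]) if deg[i] > k]
    if len(members) < 2:
        return 1.0
    e = sum(a[u, v] for u in members for v in members if u != v)
    return e / (len(members) * (len(members) - 1))


def global_efficiency_oracle(a: np.ndarray) -> float:
    d = all_pairs_distances(a)
    n = a.shape[0]
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] > 0:
                tot += 1.0 / d[i, j]
    return tot / (n * (n - 1))


def modularity_oracle(a: np.ndarray, labels: np.ndarray) -> float:
    """Q from the module-wise sum: e_c/m - (d_c/2m)^2."""
    m = a.sum() / 2
    q = 0.0
    for c in np.unique(labels):
        nodes = np.flatnonzero(labels == c)
        e_c = a[np.ix_(nodes, nodes)].sum() / 2
        d_c = a[nodes].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def participation_oracle(a: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = a[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for c in np.unique(labels):
            k_c = a[i, labels == c].sum()
            acc += (k_c / k) ** 2
        out[i] = 1 - acc
    return out


def assortativity_oracle(a: np.ndarray) -> float:
    """Pearson correlation of end-point degrees over directed edge list."""
    deg = a.sum(axis=0)
    xs, ys = [], []
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.array(xs, float), np.array(ys, float)
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def transitivity_oracle(a: np.ndarray) -> float:
    n = a.shape[0]
    closed = 0
    triples = 0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        triples += k * (k - 1) // 2
        closed += sum(1 for u, v in itertools.combinations(nbrs, 2) if a[u, v])
    return closed / triples if triples else 0.0


def random_connected_graph(n: int, rng: np.random.Generator, p=None) -> np.ndarray:
    """Random G(n, p) conditioned on connectedness (rejection sampling)."""
    while True:
        p_edge = p if p is not None else rng.uniform(0.3, 0.9)
        a = np.zeros((n, n), dtype=int)
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < p_edge:
                a[i, j] = a[j, i] = 1
        if (all_pairs_distances(a)[0] >= 0).all():
            return a
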