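"""Binary-graph measures for the functional connectome feature block.

Ten local (per-node) measures:

    betweenness centrality (raw unordered-pair counts), clustering
    coefficient, nodal path length (mean hops to reachable nodes),
    Newman and Louvain per-node modularity contributions, eccentricity,
    eigenvector centrality (unit norm), rich-club coefficient at the
    node's own degree, subgraph centrality, participation coefficient
    (w.r.t. the Louvain partition).

Thirteen global measures:

    assortativity, mean clustering, characteristic path length, Newman
    and Louvain modularity Q, the two cost-efficiency summaries (max GCE
    and the cost at the max), density, global efficiency, radius,
    diameter, transitivity, small-worldness sigma.

Per-node modularity contributions are defined as

    q_i = sum_j [a_ij - k_i k_j / (2m)] * delta(c_i, c_j) / (2m),

which sum exactly to the partition's Q — a raw module label is not a
comparable scalar feature, the contribution is.  The Newman partition is
the leading-eigenvector spectral method; Louvain is the seeded greedy
multilevel algorithm, repeated ``LOUVAIN_RESTARTS`` times keeping the
max-Q partition.  Disconnected graphs: efficiency-type measures use the
1/inf = 0 convention; path-based measures (characteristic path,
eccentricity, radius, diameter) are computed over reachable pairs on the
largest connected component, with a logged warning.  Degenerate
assortativity (regular graphs) is reported as NaN, never a silent zero.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import child_int_seed, child_rng
from .connectivity import BinaryAdjacency, GceCurve, global_efficiency_binary

logger = logging.getLogger(__name__)

LOCAL_MEASURES: tuple[str, ...] = (
    "betweenness_centrality",
    "clustering_coefficient",
    "nodal_path_length",
    "newman_module_contribution",
    "louvain_module_contribution",
    "eccentricity",
    "eigenvector_centrality",
    "rich_club_at_degree",
    "subgraph_centrality",
    "participation_coefficient",
)

GLOBAL_MEASURES: tuple[str, ...] = (
    "assortativity",
    "mean_clustering",
    "characteristic_path_length",
    "newman_Q",
    "louvain_Q",
    "gce_max",
    "gce_argmax_cost",
    "density",
    "global_efficiency",
    "radius",
    "diameter",
    "transitivity",
    "small_worldness_sigma",
)

LOUVAIN_RESTARTS = 10

# Betweenness is reported as raw unordered-pair counts (no normalization).
OUTPUT_METADATA = {
    "betweenness_normalization": "none (raw unordered source-target pair counts)",
    "nodal_path_length": "mean shortest-path hops to reachable nodes (0 if isolated)",
    "newman_module_contribution": "per-node share q_i of leading-eigenvector Q",
    "louvain_module_contribution": "per-node share q_i of best-of-10 Louvain Q",
    "rich_club_at_degree": "phi(k_i); phi = 1 where the >k subgraph has < 2 nodes",
    "participation_coefficient": "w.r.t. the Louvain partition",
}


def _to_graph(b: BinaryAdjacency | np.ndarray) -> nx.Graph:
    a = b.matrix if isinstance(b, BinaryAdjacency) else np.asarray(b)
    return nx.from_numpy_array((a > 0).astype(int))


def _distances(a: np.ndarray) -> np.ndarray:
    """All-pairs BFS hop distances; unreachable = -1."""
    adj = np.asarray(a) > 0
    n = adj.shape[0]
    out = np.full((n, n), -1, dtype=int)
    for s in range(n):
        dist = out[s]
        dist[s] = 0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        d = 0
        while frontier.any():
            d += 1
            nxt = adj[frontier].any(axis=0) & (dist < 0)
            dist[nxt] = d
            frontier = nxt
    return out


# ---------------------------------------------------------------------------
# partitions and modularity


def newman_partition(a: np.ndarray) -> np.ndarray:
    """Leading-eigenvector (spectral) community labels.

    Recursive spectral bisection of the modularity matrix
    ``B = A - k k^T / 2m`` (with the generalized matrix on subgraphs):
    each community splits by the sign of the leading eigenvector as long
    as the split increases modularity.  Dense eigendecompositions keep
    the procedure deterministic and robust at atlas scale.
    """
    a = (np.asarray(a) > 0).astype(float)
    n = a.shape[0]
    k = a.sum(axis=0)
    two_m = k.sum()
    if two_m == 0:
        return np.zeros(n, dtype=int)
    b = a - np.outer(k, k) / two_m

    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        group = stack.pop()
        if group.size < 2:
            continue
        # generalized modularity matrix for the subgroup
        bg = b[np.ix_(group, group)].copy()
        bg -= np.diag(bg.sum(axis=1))
        vals, vecs = np.linalg.eigh(bg)
        if vals[-1] <= 1e-10:
            continue
        s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
        if np.all(s == s[0]):
            continue
        dq = float(s @ bg @ s) / (2.0 * two_m)
        if dq <= 1e-12:
            continue
        part1 = group[s > 0]
        part2 = group[s < 0]
        labels[part2] = next_label
        next_label += 1
        stack.append(part1)
        stack.append(part2)
    # compact labels to 0..k-1 in order of first appearance
    _, compact = np.unique(labels, return_inverse=True)
    return compact.astype(int)


def louvain_partition(a: np.ndarray, seed: int) -> np.ndarray:
    """Seeded greedy multilevel partition, best Q of LOUVAIN_RESTARTS runs."""
    g = _to_graph(a)
    if g.number_of_edges() == 0:
        return np.zeros(g.number_of_nodes(), dtype=int)
    best_q, best = -np.inf, None
    for r in range(LOUVAIN_RESTARTS):
        communities = nx.community.louvain_communities(
            g, seed=child_int_seed(seed, "louvain", r)
        )
        q = nx.community.modularity(g, communities)
        if q > best_q:
            best_q, best = q, communities
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for c, nodes in enumerate(best):
        labels[list(nodes)] = c
    return labels


def modularity_contribution(a: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-node modularity shares q_i; sum_i q_i == Q exactly."""
    a = (np.asarray(a) > 0).astype(float)
    labels = np.asarray(labels)
    if labels.shape[0] != a.shape[0]:
        raise ValueError("partition must cover all nodes")
    k = a.sum(axis=0)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an empty graph")
    same = labels[:, None] == labels[None, :]
    b = (a - np.outer(k, k) / two_m) * same
    return b.sum(axis=1) / two_m


def modularity_q(a: np.ndarray, labels: np.ndarray) -> float:
    return float(modularity_contribution(a, labels).sum())


# ---------------------------------------------------------------------------
# individual local measures


def eigenvector_centrality(a: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the adjacency, absolute value, unit L2 norm."""
    a = (np.asarray(a) > 0).astype(float)
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, -1])
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def subgraph_centrality(a: np.ndarray) -> np.ndarray:
    """Diagonal of expm(A) via eigendecomposition."""
    a = (np.asarray(a) > 0).astype(float)
    vals, vecs = np.linalg.eigh(a)
    return (vecs**2 @ np.exp(vals)).astype(float)


def rich_club_coefficient(a: np.ndarray, k: int) -> float:
    """Density of the subgraph of nodes with degree > k (1 if < 2 nodes)."""
    a = (np.asarray(a) > 0).astype(int)
    deg = a.sum(axis=0)
    members = np.flatnonzero(deg > k)
    if members.size < 2:
        return 1.0
    sub = a[np.ix_(members, members)]
    possible = members.size * (members.size - 1)
    return float(sub.sum() / possible)


def participation_coefficient(a: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """1 - sum over modules of (within-module degree fraction)^2; 0 if isolated."""
    a = (np.asarray(a) > 0).astype(float)
    labels = np.asarray(labels)
    k = a.sum(axis=1)
    pc = np.zeros(a.shape[0])
    nz = k > 0
    for c in np.unique(labels):
        k_c = a[:, labels == c].sum(axis=1)
        pc[nz] += (k_c[nz] / k[nz]) ** 2
    pc[nz] = 1.0 - pc[nz]
    return pc


# ---------------------------------------------------------------------------
# local measures


def local_measures(b: BinaryAdjacency, seed: int = 0) -> pd.DataFrame:
    """All 10 local measures; rows = nodes, columns = LOCAL_MEASURES."""
    a = (np.asarray(b.matrix) > 0).astype(int)
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    g = _to_graph(a)
    dist = _distances(a)
    reachable = dist > 0

    if not nx.is_connected(g):
        logger.warning(
            "graph is disconnected; path-based measures use reachable pairs"
        )

    btw = nx.betweenness_centrality(g, normalized=False)
    clust = nx.clustering(g)

    npl = np.zeros(n)
    ecc = np.zeros(n)
    for i in range(n):
        d_i = dist[i][reachable[i]]
        if d_i.size:
            npl[i] = d_i.mean()
            ecc[i] = d_i.max()

    newman = newman_partition(a)
    louvain = louvain_partition(a, seed)
    deg = a.sum(axis=0)
    phi_by_k = {int(k): rich_club_coefficient(a, int(k)) for k in np.unique(deg)}

    out = pd.DataFrame(
        {
            "betweenness_centrality": [btw[i] for i in range(n)],
            "clustering_coefficient": [clust[i] for i in range(n)],
            "nodal_path_length": npl,
            "newman_module_contribution": modularity_contribution(a, newman),
            "louvain_module_contribution": modularity_contribution(a, louvain),
            "eccentricity": ecc,
            "eigenvector_centrality": eigenvector_centrality(a),
            "rich_club_at_degree": [phi_by_k[int(k)] for k in deg],
            "subgraph_centrality": subgraph_centrality(a),
            "participation_coefficient": participation_coefficient(a, louvain),
        },
        index=b.node_labels if b.node_labels else list(range(n)),
    )
    return out[list(LOCAL_MEASURES)]


# ---------------------------------------------------------------------------
# small-worldness


def _degree_preserving_rewire(
    a: np.ndarray, rng: np.random.Generator, n_attempts: int
) -> np.ndarray:
    """Double-edge-swap null model: ``n_attempts`` random swap attempts."""
    a = (np.asarray(a) > 0).astype(np.int8).copy()
    edges = [tuple(e) for e in np.argwhere(np.triu(a, k=1) > 0)]
    m = len(edges)
    if m < 2:
        return a
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        (u, v), (x, y) = edges[e1], edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed swap: (u,v),(x,y) -> (u,x),(v,y)
        if len({u, v, x, y}) < 4:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))
    return a


def _clustering_and_path(a: np.ndarray) -> tuple[float, float]:
    g = _to_graph(a)
    c = nx.average_clustering(g)
    dist = _distances(a)
    reach = dist > 0
    l = float(dist[reach].mean()) if reach.any() else np.nan
    return c, l


def small_worldness(
    b: BinaryAdjacency | np.ndarray, n_null: int = 20, seed: int = 0
) -> float:
    """sigma = (C/C_null) / (L/L_null) against degree-preserving nulls.

    Each null graph results from 10*|E| random double-edge-swap attempts;
    C_null and L_null are ensemble means.  L on a disconnected graph (null
    or observed) is the mean over reachable pairs, the same convention as
    the observed graph.
    """
    if n_null < 1:
        raise ValueError("need at least one null graph")
    a = b.matrix if isinstance(b, BinaryAdjacency) else np.asarray(b)
    a = (a > 0).astype(np.int8)
    c_obs, l_obs = _clustering_and_path(a)
    m = int(a.sum()) // 2
    rng = child_rng(seed, "small_world_nulls")
    c_nulls, l_nulls = [], []
    for _ in range(n_null):
        null = _degree_preserving_rewire(a, rng, 10 * m)
        c_n, l_n = _clustering_and_path(null)
        c_nulls.append(c_n)
        l_nulls.append(l_n)
    c_null, l_null = float(np.mean(c_nulls)), float(np.mean(l_nulls))
    if c_null == 0 or l_null == 0 or l_obs == 0:
        return np.nan
    return float((c_obs / c_null) / (l_obs / l_null))


# ---------------------------------------------------------------------------
# global measures


def global_measures(
    b: BinaryAdjacency,
    seed: int = 0,
    gce: GceCurve | None = None,
    n_null: int = 20,
) -> pd.Series:
    """All 13 global measures as a named series.

    ``gce`` is the subject's global-cost-efficiency curve from the
    weighted matrix; when omitted, the two cost-efficiency entries are
    NaN (they are properties of the weighted network, not the binary
    snapshot).
    """
    a = (np.asarray(b.matrix) > 0).astype(int)
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    g = _to_graph(a)
    if not nx.is_connected(g):
        logger.warning(
            "graph is disconnected; path measures use the largest component"
        )
        giant = max(nx.connected_components(g), key=len)
        sub = sorted(giant)
        a_lcc = a[np.ix_(sub, sub)]
    else:
        a_lcc = a

    dist = _distances(a_lcc)
    reach = dist > 0
    cpl = float(dist[reach].mean()) if reach.any() else np.nan
    ecc = np.where(
        reach.any(axis=1), np.max(np.where(reach, dist, 0), axis=1), 0
    )
    radius = float(ecc.min()) if ecc.size else np.nan
    diameter = float(ecc.max()) if ecc.size else np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            assort = float(nx.degree_assortativity_coefficient(g))
        except Exception:
            assort = np.nan
    # regular graphs have zero degree variance: report NaN, never silent 0
    if not np.isfinite(assort):
        assort = np.nan

    newman = newman_partition(a)
    louvain = louvain_partition(a, seed)

    values = {
        "assortativity": assort,
        "mean_clustering": float(nx.average_clustering(g)),
        "characteristic_path_length": cpl,
        "newman_Q": modularity_q(a, newman),
        "louvain_Q": modularity_q(a, louvain),
        "gce_max": gce.max_gce if gce is not None else np.nan,
        "gce_argmax_cost": gce.argmax_density if gce is not None else np.nan,
        "density": float(nx.density(g)),
        "global_efficiency": global_efficiency_binary(a),
        "radius": radius,
        "diameter": diameter,
        "transitivity": float(nx.transitivity(g)),
        "small_worldness_sigma": small_worldness(b, n_null=n_null, seed=seed),
    }
    return pd.Series(values)[list(GLOBAL_MEASURES)]


# ---------------------------------------------------------------------------
# cohort-level table


def subject_graph_features(
    b: BinaryAdjacency,
    seed: int = 0,
    gce: GceCurve | None = None,
    n_null: int = 20,
) -> pd.Series:
    """Flat named vector: 10 local measures per ROI followed by 13 globals."""
    loc = local_measures(b, seed=seed)
    flat = {}
    for measure in LOCAL_MEASURES:
        for roi, value in loc[measure].items():
            flat[f"{measure}__{roi}"] = float(value)
    glob = global_measures(b, seed=seed, gce=gce, n_null=n_null)
    for measure, value in glob.items():
        flat[f"global__{measure}"] = float(value)
    return pd.Series(flat)
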