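"""Functional connectivity: Pearson adjacency, GCE thresholding, binarization.

The weighted network of a subject is the matrix of Pearson correlations
between all pairs of ROI time series.  To obtain comparable binary
topologies across subjects, each weighted matrix is thresholded at a
network *density* (cost): keep the K strongest edges, where
K = round(density * N(N-1)/2).  The subject-specific optimal density is
the one maximizing global cost efficiency,

    GCE(d) = E_glob(binary graph at density d) - d,

and the cohort is binarized at the average of the per-subject optima
(19.2% in the reference analysis).  Global efficiency uses the 1/inf = 0
convention for disconnected pairs.  Negative correlations rank below
all positive ones and enter only if K exceeds the positive-edge count:
binary topological measures assume positive association.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import atlas

DEFAULT_DENSITY_GRID: np.ndarray = np.round(np.arange(0.01, 0.501, 0.01), 10)


@dataclass
class WeightedAdjacency:
    """N x N symmetric matrix of pairwise Pearson correlations, zero diagonal."""

    matrix: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if np.nanmax(np.abs(m)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.matrix = m
        if len(self.node_labels) != m.shape[0]:
            raise ValueError("node_labels length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BinaryAdjacency:
    """Binary graph at a fixed edge density."""

    matrix: np.ndarray
    density: float
    source_threshold: float
    node_labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


@dataclass
class GceCurve:
    """Global-cost-efficiency values over a density grid."""

    densities: np.ndarray
    gce_values: np.ndarray

    @property
    def argmax_density(self) -> float:
        # ties broken toward the lower density: argmax returns the first max
        return float(self.densities[int(np.argmax(self.gce_values))])

    @property
    def max_gce(self) -> float:
        return float(np.max(self.gce_values))


def pearson_adjacency(timeseries: np.ndarray, node_labels=None) -> WeightedAdjacency:
    """Pearson correlation between all column pairs; diagonal forced to 0."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a T x N matrix")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    variances = ts.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(f"zero-variance column(s): {dead.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    labels = node_labels if node_labels is not None else atlas.roi_labels(ts.shape[1])
    return WeightedAdjacency(matrix=r, node_labels=list(labels))


def _ranked_edges(w: WeightedAdjacency) -> list[tuple[int, int]]:
    """All unordered node pairs sorted by (weight desc, lexicographic pair)."""
    iu, ju = np.triu_indices(w.n_nodes, k=1)
    weights = w.matrix[iu, ju]
    order = np.lexsort((ju, iu, -weights))
    return [(int(iu[k]), int(ju[k])) for k in order]


def binarize_at_density(w: WeightedAdjacency, density: float) -> BinaryAdjacency:
    """Keep the K = round(density * N(N-1)/2) strongest edges.

    The edge ranking is by weight descending with a deterministic
    lexicographic tie-break, so the retained edge set is reproducible
    and nested across densities.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n = w.n_nodes
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(density * n_pairs + 0.5))
    if k == 0:
        raise ValueError(f"density {density} keeps zero edges on {n} nodes")
    ranked = _ranked_edges(w)
    b = np.zeros((n, n), dtype=np.int8)
    kept = ranked[:k]
    threshold = float(w.matrix[kept[-1][0], kept[-1][1]])
    for i, j in kept:
        b[i, j] = b[j, i] = 1
    return BinaryAdjacency(
        matrix=b,
        density=density,
        source_threshold=threshold,
        node_labels=list(w.node_labels),
    )


def global_efficiency_binary(matrix: np.ndarray) -> float:
    """Mean inverse shortest-path length over node pairs (1/inf = 0).

    BFS from every node on the binary adjacency; cheap at atlas scale.
    """
    a = np.asarray(matrix) > 0
    n = a.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for s in range(n):
        dist = np.full(n, -1, dtype=int)
        dist[s] = 0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        d = 0
        while frontier.any():
            d += 1
            nxt = (a[frontier].any(axis=0)) & (dist < 0)
            dist[nxt] = d
            frontier = nxt
        reach = dist > 0
        total += (1.0 / dist[reach]).sum()
    return total / (n * (n - 1))


def gce_curve(w: WeightedAdjacency, grid=None) -> GceCurve:
    """Evaluate GCE(d) = E_glob(d) - d over a density grid.

    Grid points whose edge budget rounds to zero are skipped (they have
    no defined binarization).  The argmax ties toward the lower density.
    """
    grid = DEFAULT_DENSITY_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("density grid is empty")
    grid = np.sort(grid)
    if grid[0] <= 0 or grid[-1] > 1:
        raise ValueError("grid densities must lie in (0, 1]")
    n_pairs = w.n_nodes * (w.n_nodes - 1) // 2
    ranked = _ranked_edges(w)

    densities, values = [], []
    b = np.zeros((w.n_nodes, w.n_nodes), dtype=np.int8)
    added = 0
    for d in grid:
        k = int(np.floor(d * n_pairs + 0.5))
        if k == 0:
            continue
        # densities are processed in increasing order, so edges accumulate
        for i, j in ranked[added:k]:
            b[i, j] = b[j, i] = 1
        added = max(added, k)
        densities.append(float(d))
        values.append(global_efficiency_binary(b) - float(d))
    if not densities:
        raise ValueError("no grid density keeps at least one edge")
    return GceCurve(densities=np.array(densities), gce_values=np.array(values))


# alias matching the operation's name in the pipeline documentation
gce_optimal_density = gce_curve


def cohort_average_density(curves: list[GceCurve]) -> float:
    """Arithmetic mean of per-subject GCE-optimal densities."""
    if not curves:
        raise ValueError("need at least one GCE curve")
    return float(np.mean([c.argmax_density for c in curves]))


# ---------------------------------------------------------------------------
# I/O


def write_adjacency(path, adj: WeightedAdjacency | BinaryAdjacency) -> None:
    """Square delimited text with a header row of node labels.

    Binary matrices additionally carry their density in a JSON sidecar.
    """
    path = Path(path)
    header = ",".join(adj.node_labels)
    np.savetxt(path, adj.matrix, delimiter=",", header=header, comments="")
    if isinstance(adj, BinaryAdjacency):
        sidecar = {"density": adj.density, "source_threshold": adj.source_threshold}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_weighted_adjacency(path) -> WeightedAdjacency:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().strip().split(",")
    matrix = np.loadtxt(path, delimiter=",", skiprows=1)
    return WeightedAdjacency(matrix=matrix, node_labels=labels)
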