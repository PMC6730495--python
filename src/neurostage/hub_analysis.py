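"""Centrality-consensus hub detection.

A hub is a region whose betweenness centrality OR eigenvector
centrality exceeds the across-node mean by more than two (population)
standard deviations.  Because both centralities depend on the density
at which the weighted network is binarized, hubs are flagged at every
density of a sweep (0.10 to 0.30 in steps of 0.01: 21 thresholds by
default) and a region is reported as a hub only when it is flagged at
strictly more than 85% of the thresholds (>= 18 of 21).

Group-level hubs are computed on the group's mean weighted network by
default; a per-subject voting mode is available as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import BinaryAdjacency, WeightedAdjacency, binarize_at_density
from .graph_metrics import eigenvector_centrality

DEFAULT_THRESHOLD_GRID: np.ndarray = np.round(np.arange(0.10, 0.301, 0.01), 10)
DEFAULT_CONSENSUS_CUTOFF = 0.85


def threshold_grid(start: float = 0.10, stop: float = 0.30, step: float = 0.01):
    """Inclusive density grid; the default has exactly 21 values."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


@dataclass
class HubReport:
    node_labels: list[str]
    grid: np.ndarray
    flags: np.ndarray                     # thresholds x nodes, boolean
    consensus: np.ndarray                 # per-node fraction of thresholds
    cutoff: float

    @property
    def hubs(self) -> list[str]:
        return [
            lab
            for lab, frac in zip(self.node_labels, self.consensus)
            if frac > self.cutoff
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "consensus": self.consensus,
                "is_hub": self.consensus > self.cutoff,
            },
            index=self.node_labels,
        )


def group_network(adjacencies: list[WeightedAdjacency]) -> WeightedAdjacency:
    """Elementwise mean of the subjects' weighted matrices."""
    if not adjacencies:
        raise ValueError("need at least one subject")
    shape = adjacencies[0].matrix.shape
    for w in adjacencies:
        if w.matrix.shape != shape:
            raise ValueError("adjacency shape mismatch across subjects")
    mean = np.mean([w.matrix for w in adjacencies], axis=0)
    return WeightedAdjacency(matrix=mean, node_labels=adjacencies[0].node_labels)


def hub_flags_at_threshold(w: WeightedAdjacency, density: float) -> np.ndarray:
    """Flag nodes whose betweenness or eigenvector centrality is extreme.

    The weighted network is binarized at ``density``; a node is flagged
    when either centrality is strictly larger than that measure's
    across-node mean plus two population standard deviations.
    """
    b = binarize_at_density(w, density)
    g = nx.from_numpy_array((b.matrix > 0).astype(int))
    btw = np.array(
        [v for _, v in sorted(nx.betweenness_centrality(g, normalized=False).items())]
    )
    evc = eigenvector_centrality(b.matrix)
    flags = np.zeros(w.n_nodes, dtype=bool)
    for vals in (btw, evc):
        flags |= vals > vals.mean() + 2.0 * vals.std()
    return flags


def hub_consensus(
    w: WeightedAdjacency,
    grid: np.ndarray | None = None,
    cutoff: float = DEFAULT_CONSENSUS_CUTOFF,
) -> HubReport:
    """Sweep the density grid and report consensus hub nodes."""
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("need at least one threshold")
    flags = np.stack([hub_flags_at_threshold(w, d) for d in grid])
    consensus = flags.mean(axis=0)
    return HubReport(
        node_labels=list(w.node_labels),
        grid=grid,
        flags=flags,
        consensus=consensus,
        cutoff=cutoff,
    )


def group_hubs(
    adjacencies: list[WeightedAdjacency],
    grid: np.ndarray | None = None,
    cutoff: float = DEFAULT_CONSENSUS_CUTOFF,
    mode: str = "mean_network",
) -> HubReport:
    """Hub report for one group of subjects.

    ``mode='mean_network'`` (default) computes centralities on the mean
    weighted network; ``mode='subject_vote'`` flags hubs per subject and
    takes the consensus over subjects x thresholds.
    """
    if mode == "mean_network":
        return hub_consensus(group_network(adjacencies), grid=grid, cutoff=cutoff)
    if mode == "subject_vote":
        grid_arr = (
            DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
        )
        flags = np.stack(
            [hub_flags_at_threshold(w, d) for w in adjacencies for d in grid_arr]
        )
        return HubReport(
            node_labels=list(adjacencies[0].node_labels),
            grid=grid_arr,
            flags=flags,
            consensus=flags.mean(axis=0),
            cutoff=cutoff,
        )
    raise ValueError(f"unknown mode {mode!r}")
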