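"""End-to-end orchestration: cohort -> features -> classification -> hubs.

Mirrors the staging protocol: per-subject Pearson networks, a common
binarization density equal to the cohort mean of the per-subject
GCE-optimal densities, graph measures plus anatomically- and
subject-normalized morphometry, MRMR/SFC selection inside a nested
cross-validation, and group-level centrality-consensus hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import connectivity, graph_metrics, hub_analysis, morphometry
from ._rng import child_int_seed
from .classification import ClassificationReport, NestedCvConfig, nested_cv_classify
from .morphometry import FeatureMatrix
from .synthetic_cohort import Cohort


@dataclass
class ConnectivityResult:
    weighted: dict[str, connectivity.WeightedAdjacency]
    curves: dict[str, connectivity.GceCurve]
    average_density: float
    binary: dict[str, connectivity.BinaryAdjacency]


def cohort_connectivity(
    cohort: Cohort,
    density: float | None = None,
    grid=None,
) -> ConnectivityResult:
    """Weighted networks, GCE curves, and a common-density binarization.

    ``density=None`` uses the cohort average of per-subject GCE optima.
    """
    weighted = {
        sid: connectivity.pearson_adjacency(rec.timeseries)
        for sid, rec in cohort.records.items()
    }
    curves = {
        sid: connectivity.gce_curve(w, grid=grid) for sid, w in weighted.items()
    }
    if density is None:
        density = connectivity.cohort_average_density(list(curves.values()))
    binary = {
        sid: connectivity.binarize_at_density(w, density)
        for sid, w in weighted.items()
    }
    return ConnectivityResult(
        weighted=weighted, curves=curves, average_density=density, binary=binary
    )


def cohort_feature_matrix(
    cohort: Cohort,
    conn: ConnectivityResult | None = None,
    seed: int = 0,
    n_null: int = 10,
) -> FeatureMatrix:
    """Assemble the subjects x features matrix for the whole cohort."""
    conn = conn or cohort_connectivity(cohort)
    graph_feats = {
        sid: graph_metrics.subject_graph_features(
            conn.binary[sid],
            seed=child_int_seed(seed, "metrics", sid),
            gce=conn.curves[sid],
            n_null=n_null,
        )
        for sid in cohort.records
    }
    morpho_feats = {
        sid: morphometry.normalize_morphometry(
            rec.morphometry, rec.subject_level, subject_id=sid
        )
        for sid, rec in cohort.records.items()
    }
    groups = {sid: rec.group for sid, rec in cohort.records.items()}
    return morphometry.assemble_features(graph_feats, morpho_feats, groups)


def run_staging(
    cohort: Cohort,
    seed: int = 0,
    cv_config: NestedCvConfig | None = None,
    n_null: int = 10,
    groups_to_use: list[str] | None = None,
) -> tuple[ClassificationReport, FeatureMatrix]:
    """Full pipeline: connectivity, features, nested-CV classification."""
    conn = cohort_connectivity(cohort)
    fm = cohort_feature_matrix(cohort, conn, seed=seed, n_null=n_null)
    report = nested_cv_classify(
        fm, config=cv_config, seed=seed, groups_to_use=groups_to_use
    )
    return report, fm


def group_hub_reports(
    cohort: Cohort,
    conn: ConnectivityResult | None = None,
    grid=None,
    cutoff: float = hub_analysis.DEFAULT_CONSENSUS_CUTOFF,
    mode: str = "mean_network",
) -> dict[str, hub_analysis.HubReport]:
    """Hub consensus per diagnostic group."""
    conn = conn or cohort_connectivity(cohort)
    groups = sorted({rec.group for rec in cohort.records.values()})
    out = {}
    for g in groups:
        adjacencies = [
            conn.weighted[sid]
            for sid, rec in cohort.records.items()
            if rec.group == g
        ]
        out[g] = hub_analysis.group_hubs(
            adjacencies, grid=grid, cutoff=cutoff, mode=mode
        )
    return out
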