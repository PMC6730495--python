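"""Synthetic multimodal cohort generator.

Generates a labelled cohort of subjects — BOLD-like ROI time series plus
FreeSurfer-style morphometric tables — with the statistical structure the
downstream staging analysis assumes:

* four diagnostic groups (AD, MCI-C, MCI-NC, HC) with configurable sizes,
  defaulting to the 34/25/69/49 composition of the reference cohort;
* per-group modular ground-truth networks (stochastic block models),
  from which time series are drawn so that connected region pairs are
  more correlated than unconnected ones;
* group-shifted morphometric means on a designated region subset, with
  inflated between-subject variance in the MCI groups (feature values
  cluster tightly in AD/HC but scatter in MCI);
* optionally planted hub nodes whose degree exceeds the rest of the
  network by at least three standard deviations.

Time-series model: rows are i.i.d. draws from N(0, Sigma) with
``Sigma = I + rho * A / (lambda_max(A) + eps)``, which is symmetric
positive definite for any binary adjacency ``A`` and any ``0 <= rho < 1``,
and links edges monotonically to pairwise correlations.  Units are
nominal (mm, mm^2, mm^3) purely to exercise normalization; no anatomical
realism is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import atlas
from ._rng import child_rng

GROUPS: tuple[str, ...] = ("AD", "MCI-C", "MCI-NC", "HC")

DEFAULT_GROUP_SIZES: dict[str, int] = {"AD": 34, "MCI-C": 25, "MCI-NC": 69, "HC": 49}

MANIFEST_SCHEMA_VERSION = 1

# Fixture population constants for FreeSurfer-style quantities
# (mean, SD) in the units given; chosen to be plausible in scale only.
MORPHO_POPULATION: dict[str, tuple[float, float]] = {
    "area": (950.0, 120.0),          # mm^2 per cortical parcel
    "curvature": (0.13, 0.02),       # 1/mm
    "thickness_mean": (2.50, 0.25),  # mm
    "thickness_sd": (0.55, 0.08),    # mm
    "volume": (2300.0, 350.0),       # mm^3 per cortical parcel
}
SUBCORTICAL_POPULATION: tuple[float, float] = (4000.0, 600.0)  # mm^3
ETIV_POPULATION: tuple[float, float] = (1.5e6, 1.3e5)          # mm^3


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass(frozen=True)
class ModuleSpec:
    """Stochastic-block-model specification for one group's network.

    ``partition`` lists the modules as tuples of node indices; together
    they must cover ``0..n_regions-1`` exactly once.
    """

    partition: tuple[tuple[int, ...], ...]
    p_within: float
    p_between: float

    def validate(self, n_regions: int) -> None:
        if not (0.0 <= self.p_within <= 1.0 and 0.0 <= self.p_between <= 1.0):
            raise ConfigurationError("edge probabilities must lie in [0, 1]")
        seen = sorted(i for module in self.partition for i in module)
        if seen != list(range(n_regions)):
            raise ConfigurationError(
                "module partition must cover all regions exactly once"
            )

    def labels(self, n_regions: int) -> np.ndarray:
        lab = np.empty(n_regions, dtype=int)
        for m, module in enumerate(self.partition):
            lab[list(module)] = m
        return lab


def even_partition(n_regions: int, n_modules: int) -> tuple[tuple[int, ...], ...]:
    """Split ``0..n_regions-1`` into ``n_modules`` contiguous near-equal blocks."""
    bounds = np.linspace(0, n_regions, n_modules + 1).round().astype(int)
    return tuple(
        tuple(range(bounds[m], bounds[m + 1])) for m in range(n_modules)
    )


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    group_sizes
        Subjects per diagnostic group.
    n_regions, n_timepoints
        Dimensions of each subject's time-series matrix (volumes x ROIs).
    module_spec
        Per-group ground-truth network structure.
    coupling
        rho in [0, 1): strength of the link between ground-truth edges
        and time-series correlations.
    morpho_effect
        Per-group mean shift, in population-SD units, applied to the
        ``morpho_measures`` of the cortical regions in ``morpho_regions``.
    mci_heterogeneity
        Variance multiplier for the planted morphometric features of the
        MCI groups (>=1 scatters MCI subjects relative to AD/HC).
    hub_spec
        (group, node) pairs given elevated degree in that group's graph.
    hub_strength
        Coupling multiplier for edges incident to a planted hub.  Real
        cortical hubs are distinguished by strong connections as much as
        by numerous ones; without the strength grading a degree-only hub
        does not survive thresholding at densities below the graph's own
        density (the covariance model gives every edge the same
        correlation, so sub-density thresholds keep an arbitrary subset).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_regions: int = 160
    n_timepoints: int = 140
    module_spec: dict[str, ModuleSpec] = field(default_factory=dict)
    coupling: float = 0.5
    morpho_effect: dict[str, float] = field(default_factory=dict)
    morpho_regions: tuple[int, ...] = ()
    morpho_measures: tuple[str, ...] = ("thickness_mean", "volume")
    mci_heterogeneity: float = 1.0
    hub_spec: tuple[tuple[str, int], ...] = ()
    hub_strength: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.module_spec:
            self.module_spec = default_module_spec(self.n_regions)
        self.validate()

    def validate(self) -> None:
        for group, n in self.group_sizes.items():
            if n < 1:
                raise ConfigurationError(f"group {group!r} has size {n} < 1")
        if not (0.0 <= self.coupling < 1.0):
            raise ConfigurationError("coupling rho must satisfy 0 <= rho < 1")
        for group, spec in self.module_spec.items():
            spec.validate(self.n_regions)
        for group, node in self.hub_spec:
            if not (0 <= node < self.n_regions):
                raise ConfigurationError(f"hub node {node} out of range")

    def spec_for(self, group: str) -> ModuleSpec:
        try:
            return self.module_spec[group]
        except KeyError:
            raise ConfigurationError(f"no module_spec for group {group!r}") from None


def default_module_spec(n_regions: int) -> dict[str, ModuleSpec]:
    """Group-dependent modular structure.

    HC has the crispest modularity; AD has weakened within-module and
    elevated between-module connectivity (the disconnection-syndrome
    pattern); the MCI groups sit in between.
    """
    n_modules = max(2, round(n_regions / 20))
    part = even_partition(n_regions, n_modules)
    return {
        "HC": ModuleSpec(part, p_within=0.60, p_between=0.05),
        "MCI-NC": ModuleSpec(part, p_within=0.55, p_between=0.06),
        "MCI-C": ModuleSpec(part, p_within=0.50, p_between=0.07),
        "AD": ModuleSpec(part, p_within=0.45, p_between=0.08),
    }


@dataclass
class SubjectRecord:
    """One subject's raw data: BOLD-like time series plus morphometry."""

    subject_id: str
    group: str
    timeseries: np.ndarray                # T x N
    morphometry: pd.DataFrame             # 148 rows: region-level table
    subject_level: dict[str, float]       # eTIV, hemi totals, 34 subcortical


@dataclass
class CohortManifest:
    subjects: list[dict]                  # {subject_id, group}
    seed: int
    schema_version: int = MANIFEST_SCHEMA_VERSION

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "schema_version": self.schema_version,
                "seed": self.seed,
                "subjects": self.subjects,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "CohortManifest":
        doc = yaml.safe_load(text)
        return cls(
            subjects=doc["subjects"],
            seed=doc["seed"],
            schema_version=doc["schema_version"],
        )


@dataclass
class Cohort:
    config: CohortConfig
    manifest: CohortManifest
    records: dict[str, SubjectRecord]
    group_graphs: dict[str, np.ndarray]   # per-group ground-truth adjacency

    def subjects_in(self, group: str) -> list[SubjectRecord]:
        return [r for r in self.records.values() if r.group == group]


# ---------------------------------------------------------------------------
# ground-truth graphs


def generate_ground_truth_graph(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> np.ndarray:
    """Binary N x N adjacency for one group: SBM plus planted hubs.

    Hub nodes listed in ``config.hub_spec`` for this group receive
    additional uniformly random edges until their degree exceeds the
    mean of the remaining degrees by at least 3 of their SDs.
    """
    if group not in config.group_sizes:
        raise ConfigurationError(f"unknown group {group!r}")
    spec = config.spec_for(group)
    n = config.n_regions
    labels = spec.labels(n)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    p = np.where(same, spec.p_within, spec.p_between)
    edges = rng.random(p.size) < p
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[0][edges], iu[1][edges]] = 1
    a = a + a.T

    hub_nodes = [node for g, node in config.hub_spec if g == group]
    for node in hub_nodes:
        _boost_hub(a, node, rng)
    return a


def _boost_hub(a: np.ndarray, node: int, rng: np.random.Generator) -> None:
    n = a.shape[0]
    others = np.array([i for i in range(n) if i != node])
    while True:
        deg = a.sum(axis=0)
        rest = deg[others]
        mu, sd = rest.mean(), rest.std()
        if deg[node] > mu + 3.0 * sd:
            return
        candidates = others[a[node, others] == 0]
        if candidates.size == 0:          # already fully connected
            return
        j = rng.choice(candidates)
        a[node, j] = a[j, node] = 1


# ---------------------------------------------------------------------------
# time series


def generate_timeseries(
    adjacency: np.ndarray,
    n_timepoints: int,
    coupling: float,
    rng: np.random.Generator,
    eps: float = 1e-6,
) -> np.ndarray:
    """T x N Gaussian time series whose covariance tracks the adjacency.

    Rows are i.i.d. N(0, Sigma) with
    ``Sigma = I + coupling * A / (lambda_max(A) + eps)``.  Since the
    scaled matrix has spectral radius < 1, Sigma is positive definite
    for any symmetric binary or nonnegative-weighted ``A`` and any
    ``0 <= coupling < 1``.
    """
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for meaningful correlations")
    if not (0.0 <= coupling < 1.0):
        raise ValueError("coupling must satisfy 0 <= coupling < 1")
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be a symmetric square matrix")
    n = a.shape[0]
    sigma = np.eye(n)
    if coupling > 0 and a.any():
        lam_max = float(np.linalg.eigvalsh(a)[-1])
        sigma = sigma + coupling * a / (lam_max + eps)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n_timepoints, n))
    return z @ chol.T


# ---------------------------------------------------------------------------
# morphometry


def _generate_morphometry(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, float]]:
    regions = atlas.cortical_regions()
    het = config.mci_heterogeneity if group.startswith("MCI") else 1.0
    shift = config.morpho_effect.get(group, 0.0)
    shifted = set(config.morpho_regions)

    table: dict[str, list] = {
        "region": [name for _, name in regions],
        "hemisphere": [hemi for hemi, _ in regions],
    }
    for measure, (mu, sd) in MORPHO_POPULATION.items():
        noise_sd = sd * np.sqrt(het) if measure in config.morpho_measures else sd
        vals = mu + rng.normal(0.0, noise_sd, size=len(regions))
        if shift != 0.0 and measure in config.morpho_measures and shifted:
            idx = [i for i in shifted if i < len(regions)]
            vals[idx] += shift * sd
        # physical quantities stay positive; nominal floor at 1% of mean
        if measure != "curvature":
            vals = np.maximum(vals, 0.01 * mu)
        table[measure] = list(vals)
    morpho = pd.DataFrame(table)

    sub_mu, sub_sd = SUBCORTICAL_POPULATION
    sub_vals = np.maximum(
        sub_mu + rng.normal(0.0, sub_sd, size=len(atlas.SUBCORTICAL_STRUCTURES)),
        0.01 * sub_mu,
    )
    etiv_mu, etiv_sd = ETIV_POPULATION
    etiv = max(etiv_mu + rng.normal(0.0, etiv_sd), 0.5 * etiv_mu)
    subject_level: dict[str, float] = {"eTIV": float(etiv)}
    for hemi in ("lh", "rh"):
        mask = morpho["hemisphere"] == hemi
        subject_level[f"{hemi}_total_area"] = float(morpho.loc[mask, "area"].sum())
    for name, v in zip(atlas.SUBCORTICAL_STRUCTURES, sub_vals):
        subject_level[name] = float(v)
    return morpho, subject_level


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: CohortConfig) -> Cohort:
    """One record per subject, all randomness derived from ``config.seed``."""
    seed = config.seed
    group_graphs: dict[str, np.ndarray] = {}
    records: dict[str, SubjectRecord] = {}
    manifest_rows: list[dict] = []

    for group, n_subjects in config.group_sizes.items():
        graph_rng = child_rng(seed, "graph", group)
        adjacency = generate_ground_truth_graph(config, group, graph_rng)
        group_graphs[group] = adjacency
        coupled = adjacency.astype(float)
        for g, node in config.hub_spec:
            # hub edges are strong as well as numerous
            if g == group:
                coupled[node, :] *= config.hub_strength
                coupled[:, node] *= config.hub_strength
        for i in range(n_subjects):
            subject_id = f"{group}_{i + 1:03d}"
            if subject_id in records:
                raise ConfigurationError(f"duplicate subject id {subject_id!r}")
            ts_rng = child_rng(seed, "timeseries", group, i)
            ts = generate_timeseries(
                coupled, config.n_timepoints, config.coupling, ts_rng
            )
            morpho_rng = child_rng(seed, "morphometry", group, i)
            morpho, subject_level = _generate_morphometry(config, group, morpho_rng)
            records[subject_id] = SubjectRecord(
                subject_id=subject_id,
                group=group,
                timeseries=ts,
                morphometry=morpho,
                subject_level=subject_level,
            )
            manifest_rows.append({"subject_id": subject_id, "group": group})

    manifest = CohortManifest(subjects=manifest_rows, seed=seed)
    return Cohort(
        config=config, manifest=manifest, records=records, group_graphs=group_graphs
    )


# ---------------------------------------------------------------------------
# named study configurations


def default_config(seed: int = 0) -> CohortConfig:
    """The full-scale cohort: 34/25/69/49 subjects, 160 ROIs, 140 volumes."""
    return CohortConfig(seed=seed)


def reduced_config(
    seed: int = 0,
    n_per_group: int = 15,
    n_regions: int = 32,
    coupling: float = 0.5,
    morpho_sd_shift: float = 1.5,
    mci_heterogeneity: float = 4.0,
) -> CohortConfig:
    """Reduced-scale strong-effect cohort used for end-to-end checks.

    Four groups of ``n_per_group`` subjects, 32 regions, 140 volumes.
    Group-graded morphometric shifts (AD most atrophic, HC unshifted) on
    a 10-region subset, with the MCI groups' planted features scattered
    by a 4x variance inflation; group-dependent modular networks as in
    :func:`default_module_spec`.
    """
    return CohortConfig(
        group_sizes={g: n_per_group for g in GROUPS},
        n_regions=n_regions,
        n_timepoints=140,
        coupling=coupling,
        morpho_effect={"AD": -2.0 * morpho_sd_shift / 1.5,
                       "MCI-C": -1.2 * morpho_sd_shift / 1.5,
                       "MCI-NC": -0.6 * morpho_sd_shift / 1.5,
                       "HC": 0.0},
        morpho_regions=tuple(range(10)),
        mci_heterogeneity=mci_heterogeneity,
        seed=seed,
    )


def null_config(seed: int = 0, n_per_group: int = 15, n_regions: int = 32) -> CohortConfig:
    """Null cohort: no coupling, no morphometric effect, no hubs.

    Downstream group classification on this cohort should sit at chance;
    it is the honesty check for the whole pipeline.
    """
    part = even_partition(n_regions, max(2, n_regions // 8))
    flat = {g: ModuleSpec(part, p_within=0.2, p_between=0.2) for g in GROUPS}
    return CohortConfig(
        group_sizes={g: n_per_group for g in GROUPS},
        n_regions=n_regions,
        n_timepoints=140,
        module_spec=flat,
        coupling=0.0,
        morpho_effect={},
        mci_heterogeneity=1.0,
        seed=seed,
    )


def hub_config(
    seed: int = 0,
    n_per_group: int = 12,
    n_regions: int = 32,
    hub_node: int = 0,
    hub_group: str = "HC",
    coupling: float = 0.6,
) -> CohortConfig:
    """Cohort with one planted hub, for hub-recovery checks.

    The ground-truth density (~0.3) sits at the top of the standard
    0.10-0.30 hub sweep, so every sweep threshold probes true structure
    rather than sampling noise.
    """
    part = even_partition(n_regions, 4)
    spec = {g: ModuleSpec(part, p_within=0.80, p_between=0.12) for g in GROUPS}
    return CohortConfig(
        group_sizes={g: n_per_group for g in GROUPS},
        n_regions=n_regions,
        n_timepoints=140,
        module_spec=spec,
        coupling=coupling,
        hub_spec=((hub_group, hub_node),),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write manifest (YAML), per-subject time series and morphometry (CSV)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.yaml").write_text(cohort.manifest.to_yaml())
    for sid, rec in cohort.records.items():
        np.savetxt(out / f"{sid}_timeseries.csv", rec.timeseries, delimiter=",")
        rec.morphometry.to_csv(out / f"{sid}_morphometry.csv", index=False)
        pd.Series(rec.subject_level).rename("value").to_csv(
            out / f"{sid}_subject_level.csv", index_label="name"
        )


def read_cohort(indir) -> tuple[CohortManifest, dict[str, SubjectRecord]]:
    """Read a cohort previously written by :func:`write_cohort`."""
    from pathlib import Path

    ind = Path(indir)
    manifest = CohortManifest.from_yaml((ind / "manifest.yaml").read_text())
    records: dict[str, SubjectRecord] = {}
    for row in manifest.subjects:
        sid, group = row["subject_id"], row["group"]
        ts = np.loadtxt(ind / f"{sid}_timeseries.csv", delimiter=",")
        morpho = pd.read_csv(ind / f"{sid}_morphometry.csv")
        sl = pd.read_csv(ind / f"{sid}_subject_level.csv", index_col="name")[
            "value"
        ].to_dict()
        records[sid] = SubjectRecord(
            subject_id=sid,
            group=group,
            timeseries=ts,
            morphometry=morpho,
            subject_level=sl,
        )
    return manifest, records
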