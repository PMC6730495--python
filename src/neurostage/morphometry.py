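"""Structural-MRI feature block and multimodal feature assembly.

The structural block per subject is 5 measures x 148 cortical areas
plus 34 subcortical volumes (774 values).  Anatomical normalization
makes subjects comparable: volumes are divided by the subject's
estimated total intracranial volume (eTIV) and areas by the total area
of the same hemisphere; thickness and curvature need no anatomical
normalization and pass through unchanged.  After feature extraction
each subject's features are normalized individually (z-score within
each modality block), so the functional and structural blocks are
commensurate before fusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

CORTICAL_MEASURES: tuple[str, ...] = (
    "area",
    "curvature",
    "thickness_mean",
    "thickness_sd",
    "volume",
)

NORMALIZED_BY: dict[str, str] = {
    "area": "hemisphere_total_area",
    "curvature": "none",
    "thickness_mean": "none",
    "thickness_sd": "none",
    "volume": "eTIV",
}

MODALITY_RSFMRI = "rsfmri"
MODALITY_SMRI = "smri"


class MorphometryError(ValueError):
    pass


def normalize_morphometry(
    morpho: pd.DataFrame,
    subject_level: dict[str, float],
    subject_id: str = "<unknown>",
) -> pd.Series:
    """Anatomically normalized structural feature vector for one subject.

    Parameters
    ----------
    morpho
        Region table with columns region, hemisphere, area, curvature,
        thickness_mean, thickness_sd, volume (one row per cortical area).
    subject_level
        eTIV, lh_total_area, rh_total_area and the named subcortical
        volumes (mm^3).

    Returns a named series: for each cortical area the five measures
    (area and volume normalized, the rest raw), then each subcortical
    volume divided by eTIV.
    """
    etiv = float(subject_level["eTIV"])
    if etiv <= 0:
        raise MorphometryError(f"subject {subject_id}: nonpositive eTIV {etiv}")
    totals = {}
    for hemi in ("lh", "rh"):
        tot = float(subject_level[f"{hemi}_total_area"])
        if tot <= 0:
            raise MorphometryError(
                f"subject {subject_id}: nonpositive {hemi} total area {tot}"
            )
        totals[hemi] = tot

    values: dict[str, float] = {}
    for _, row in morpho.iterrows():
        label = f"{row['hemisphere']}_{row['region']}"
        for measure in CORTICAL_MEASURES:
            raw = float(row[measure])
            if measure == "volume":
                v = raw / etiv
            elif measure == "area":
                v = raw / totals[row["hemisphere"]]
            else:
                v = raw
            values[f"{measure}__{label}"] = v
    subcortical = [
        k
        for k in subject_level
        if k not in ("eTIV", "lh_total_area", "rh_total_area")
    ]
    for name in subcortical:
        values[f"subcortical_volume__{name}"] = float(subject_level[name]) / etiv
    return pd.Series(values)


def per_subject_normalize(
    features: pd.Series, modality_tags: pd.Series
) -> pd.Series:
    """Z-score each modality block of one subject's feature vector.

    Within each block the mean becomes 0 and the population SD becomes 1
    across that subject's own features.  A zero-variance block is a hard
    error: it carries no information and would divide by zero.
    Idempotent (z of z is z, to numerical tolerance).
    """
    out = features.astype(float).copy()
    for modality in modality_tags.unique():
        idx = modality_tags[modality_tags == modality].index
        if len(idx) < 2:
            raise MorphometryError(
                f"modality block {modality!r} has fewer than 2 features"
            )
        block = out.loc[idx].to_numpy()
        sd = block.std()
        if sd == 0:
            raise MorphometryError(f"modality block {modality!r} has zero variance")
        out.loc[idx] = (block - block.mean()) / sd
    return out


@dataclass
class FeatureMatrix:
    """Subjects x features with modality tags and group labels."""

    data: pd.DataFrame              # index subject_id, columns feature names
    modality: pd.Series             # feature name -> rsfmri | smri
    groups: pd.Series               # subject_id -> group label
    normalization: dict             # per-subject normalization record

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise MorphometryError(f"missing values in features: {bad[:5]} ...")
        if self.data.columns.duplicated().any():
            raise MorphometryError("feature names must be unique")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def block(self, modality: str) -> pd.DataFrame:
        cols = self.modality[self.modality == modality].index
        return self.data[cols]

    def to_csv(self, path, sidecar_path=None) -> None:
        self.data.assign(group=self.groups).to_csv(path, index_label="subject_id")
        if sidecar_path is not None:
            meta = {
                "schema_version": 1,
                "modality": self.modality.to_dict(),
                "normalization": self.normalization,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh)


def assemble_features(
    graph_features: dict[str, pd.Series],
    morpho_features: dict[str, pd.Series],
    groups: dict[str, str],
    normalize: bool = True,
) -> FeatureMatrix:
    """Fuse per-subject graph and structural vectors into one matrix.

    Every subject in ``groups`` must appear in both feature inputs; the
    column order (all rs-fMRI graph features, then all sMRI features) is
    deterministic.  With ``normalize=True`` each subject's features are
    z-scored per modality block before assembly.
    """
    missing = [
        s for s in groups if s not in graph_features or s not in morpho_features
    ]
    if missing:
        raise MorphometryError(f"subjects missing from inputs: {missing}")

    subject_ids = list(groups)
    g0 = graph_features[subject_ids[0]]
    m0 = morpho_features[subject_ids[0]]
    columns = list(g0.index) + list(m0.index)
    modality = pd.Series(
        [MODALITY_RSFMRI] * len(g0) + [MODALITY_SMRI] * len(m0), index=columns
    )

    rows = []
    for sid in subject_ids:
        vec = pd.concat([graph_features[sid], morpho_features[sid]])[columns]
        if normalize:
            vec = per_subject_normalize(vec, modality)
        rows.append(vec.rename(sid))
    data = pd.DataFrame(rows)
    record = {
        "per_subject": "z-score within modality block" if normalize else "none",
        "anatomical": dict(NORMALIZED_BY),
    }
    return FeatureMatrix(
        data=data,
        modality=modality,
        groups=pd.Series(groups),
        normalization=record,
    )
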