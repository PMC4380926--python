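"""Fisher-score-weighted PCA deviation spaces and deviation indices.

A deviation space is a frozen transform built from a feature-selected
matrix: each feature is z-scored across all retained samples, scaled by
its Fisher score (between-group over within-group variability, computed
baseline vs disease), and the weighted matrix is rotated by a full-rank
PCA.  All principal components are kept, so the rotation is an isometry:
distances in the rotated space equal Fisher-weighted Euclidean distances
in z-space.  A sample's deviation index (TDI for expression, GPDI for the
physiological panel, MDI for metabolites) is its Euclidean distance to the
baseline-group centroid in that space; the per-marker PDI is simply
|marker value - baseline-group mean|.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import GroupDesign, OmicsMatrix, ValidationError

logger = logging.getLogger("devindex")


def fisher_scores(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized Fisher score per column of two group matrices.

    F = sum_k n_k (mu_k - mu)^2 / sum_k n_k sigma_k^2 with sigma_k the
    sample (n-1 denominator) standard deviation and mu the mean over the
    union of both groups.
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 values for a Fisher score")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    mu = (n1 * m1 + n2 * m2) / (n1 + n2)
    num = n1 * (m1 - mu) ** 2 + n2 * (m2 - mu) ** 2
    den = n1 * x1.var(axis=0, ddof=1) + n2 * x2.var(axis=0, ddof=1)
    zero = den == 0.0
    if np.any(zero & (num > 0.0)):
        raise ValidationError("Fisher score undefined: zero within-group variance, unequal means")
    if np.any(zero):
        logger.warning("Fisher score 0 for feature(s) with zero variance and equal means")
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~zero)
    return out


def fisher_score(values, labels) -> float:
    """Fisher score of one feature given per-sample values and two-group labels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValidationError("Fisher score needs exactly two groups")
    x1 = values[labels == uniq[0]][:, None]
    x2 = values[labels == uniq[1]][:, None]
    return float(fisher_scores(x1, x2)[0])


@dataclass(frozen=True)
class DeviationSpace:
    """Frozen transform: features, z-parameters, weights, rotation, centroids.

    ``rotation`` is an orthonormal p x p matrix (all principal components),
    so the projection is an isometry of the weighted z-space.  New samples
    are mapped with the stored z-parameters and weights, centered at the
    stored grand mean, and rotated.
    """

    name: str
    feature_ids: tuple[str, ...]
    z_mean: np.ndarray
    z_sd: np.ndarray
    weights: np.ndarray
    rotation: np.ndarray
    grand_mean: np.ndarray  # of the weighted z matrix, pre-rotation
    baseline_centroid: np.ndarray  # rotated coordinates
    disease_centroid: np.ndarray
    retained_sample_ids: tuple[str, ...]
    baseline_group: str
    disease_group: str

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    # -- projection --------------------------------------------------------
    def transform(self, data: pd.DataFrame | OmicsMatrix) -> pd.DataFrame:
        """Project samples (rows) into rotated coordinates."""
        df = data.data if isinstance(data, OmicsMatrix) else data
        missing = [f for f in self.feature_ids if f not in df.columns]
        if missing:
            raise ValidationError(f"sample(s) missing feature {missing[0]!r}")
        x = df.loc[:, list(self.feature_ids)].to_numpy(dtype=float)
        if np.isnan(x).any():
            j = int(np.argwhere(np.isnan(x))[0, 1])
            raise ValidationError(f"missing value for feature {self.feature_ids[j]!r}")
        z = (x - self.z_mean) / self.z_sd
        coords = (z * self.weights - self.grand_mean) @ self.rotation
        return pd.DataFrame(coords, index=df.index)

    def index_of(self, coords: np.ndarray) -> np.ndarray:
        """Euclidean distance of rotated coordinates to the baseline centroid."""
        coords = np.atleast_2d(coords)
        return np.linalg.norm(coords - self.baseline_centroid, axis=1)

    # -- provenance sidecar ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "feature_ids": list(self.feature_ids),
            "z_mean": self.z_mean.tolist(),
            "z_sd": self.z_sd.tolist(),
            "weights": self.weights.tolist(),
            "rotation": self.rotation.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "baseline_centroid": self.baseline_centroid.tolist(),
            "disease_centroid": self.disease_centroid.tolist(),
            "retained_sample_ids": list(self.retained_sample_ids),
            "baseline_group": self.baseline_group,
            "disease_group": self.disease_group,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DeviationSpace":
        d = json.loads(Path(path).read_text())
        arrays = {
            k: np.asarray(d[k], dtype=float)
            for k in ("z_mean", "z_sd", "weights", "rotation", "grand_mean",
                      "baseline_centroid", "disease_centroid")
        }
        return cls(
            name=d["name"],
            feature_ids=tuple(d["feature_ids"]),
            retained_sample_ids=tuple(d["retained_sample_ids"]),
            baseline_group=d["baseline_group"],
            disease_group=d["disease_group"],
            **arrays,
        )


def build_deviation_space(
    data: OmicsMatrix,
    design: GroupDesign,
    weighting_mode: str = "fisher",
    weight_exponent: float = 1.0,
    name: str = "space",
) -> DeviationSpace:
    """Construct a deviation space from a (feature-restricted) matrix.

    Steps: (1) drop samples with any missing value among the space's
    features (the GPDI completeness rule), logging each; (2) z-score every
    feature across all retained samples; (3) scale each column by its
    Fisher score between baseline and disease groups raised to
    ``weight_exponent`` (all weights 1 in ``equal`` mode); (4) rotate by a
    full-rank PCA of the weighted matrix; (5) store the baseline and
    disease centroids in rotated coordinates.  Zero-variance features are
    dropped with a warning.
    """
    design.check_covers(data)
    retained = data.drop_incomplete_samples()
    base = design.samples_of(design.baseline_group, within=retained.sample_ids)
    dis = design.samples_of(design.disease_group, within=retained.sample_ids)
    if len(base) < 2:
        raise ValidationError("fewer than 2 baseline samples after exclusions")
    if len(dis) < 2:
        raise ValidationError("fewer than 2 disease samples after exclusions")

    x = retained.values
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0.0
    for fid in np.asarray(retained.feature_ids)[~keep]:
        logger.warning("dropping zero-variance feature %s", fid)
    if not keep.any():
        raise ValidationError("no features with nonzero variance")
    feature_ids = tuple(np.asarray(retained.feature_ids)[keep])
    x = x[:, keep]
    mean, sd = x.mean(axis=0), sd[keep]
    z = (x - mean) / sd

    idx = {s: i for i, s in enumerate(retained.sample_ids)}
    zb = z[[idx[s] for s in base]]
    zd = z[[idx[s] for s in dis]]
    if weighting_mode == "fisher":
        weights = fisher_scores(zd, zb) ** weight_exponent
    elif weighting_mode == "equal":
        weights = np.ones(len(feature_ids))
    else:
        raise ValidationError(f"unknown weighting_mode {weighting_mode!r}")

    weighted = z * weights
    grand_mean = weighted.mean(axis=0)
    centered = weighted - grand_mean
    # full_matrices=True yields a complete orthonormal basis of feature
    # space even when n_samples < n_features (all components retained)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    rotation = vt.T
    coords = centered @ rotation
    baseline_centroid = coords[[idx[s] for s in base]].mean(axis=0)
    disease_centroid = coords[[idx[s] for s in dis]].mean(axis=0)
    logger.info(
        "built space %s: %d samples (%d excluded), %d features, mode=%s",
        name, len(retained.sample_ids), data.shape[0] - len(retained.sample_ids),
        len(feature_ids), weighting_mode,
    )
    return DeviationSpace(
        name=name,
        feature_ids=feature_ids,
        z_mean=mean,
        z_sd=sd,
        weights=weights,
        rotation=rotation,
        grand_mean=grand_mean,
        baseline_centroid=baseline_centroid,
        disease_centroid=disease_centroid,
        retained_sample_ids=tuple(retained.sample_ids),
        baseline_group=design.baseline_group,
        disease_group=design.disease_group,
    )


def deviation_index(space: DeviationSpace, sample: Mapping[str, float] | pd.Series) -> float:
    """Deviation index of a single sample (distance to baseline centroid)."""
    row = pd.DataFrame([pd.Series(dict(sample))])
    coords = space.transform(row).to_numpy()
    return float(space.index_of(coords)[0])


def index_table(
    space: DeviationSpace,
    data: OmicsMatrix,
    design: GroupDesign,
    label: str,
) -> pd.DataFrame:
    """Per-sample deviation indices for every retained sample of the space.

    Returns a DataFrame with columns sample_id, group, index and a
    ``label`` attribute naming the space kind (e.g. TDI-liver, GPDI).
    """
    sub = data.data.loc[list(space.retained_sample_ids), list(space.feature_ids)]
    coords = space.transform(sub).to_numpy()
    out = pd.DataFrame(
        {
            "sample_id": space.retained_sample_ids,
            "group": [design.group(s) for s in space.retained_sample_ids],
            "index": space.index_of(coords),
        }
    )
    out.attrs["label"] = label
    return out


def pdi_table(markers: OmicsMatrix, design: GroupDesign) -> pd.DataFrame:
    """Per-sample, per-marker deviation: |value - baseline-group mean|.

    Missing marker values yield missing PDIs; the sample is retained for
    its other markers.  A marker with no baseline values at all gives an
    all-missing column with a warning.
    """
    design.check_covers(markers)
    base = design.samples_of(design.baseline_group, within=markers.sample_ids)
    if not base:
        raise ValidationError("no baseline samples in marker table")
    base_mean = markers.data.loc[base].mean(axis=0, skipna=True)
    for mk in base_mean.index[base_mean.isna()]:
        logger.warning("marker %s has no baseline values; PDI all-missing", mk)
    return (markers.data - base_mean).abs()
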