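"""Restorative / non-restorative decomposition of treatment effects.

The disease-reversal axis is the unit vector from the disease-group
centroid toward the baseline centroid.  A treated sample's displacement v
(by default taken relative to the disease centroid) splits into two
orthogonal parts: v1 = (u . v) u along the axis, whose signed scalar s
measures progress from the untreated disease state toward the healthy
baseline, and v2 = v - v1, the non-restorative component.  Large ||v2||
flags off-target effects orthogonal to disease reversal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GroupDesign, OmicsMatrix, ValidationError
from .space import DeviationSpace

_ORIGINS = ("disease", "grand_mean")


def reversal_axis(space: DeviationSpace) -> np.ndarray:
    """Unit vector from the disease centroid toward the baseline centroid."""
    d = space.baseline_centroid - space.disease_centroid
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValidationError("degenerate reversal axis: coincident centroids")
    return d / norm


def decompose(
    space: DeviationSpace,
    coords: np.ndarray,
    origin: str = "disease",
) -> tuple[float, float, float]:
    """Decompose one sample's rotated coordinates into (s, ||v1||, ||v2||).

    ``origin`` picks the reference point of the displacement v: the
    disease centroid (default; s = 0 for the untreated disease state) or
    the grand mean of the space.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != space.baseline_centroid.shape:
        raise ValidationError(
            f"dimension mismatch: sample has {coords.shape}, space needs "
            f"{space.baseline_centroid.shape}"
        )
    if origin not in _ORIGINS:
        raise ValidationError(f"unknown origin {origin!r}")
    ref = space.disease_centroid if origin == "disease" else np.zeros_like(coords)
    u = reversal_axis(space)
    v = coords - ref
    s = float(u @ v)
    v2 = v - s * u
    return s, abs(s), float(np.linalg.norm(v2))


def decomposition_table(
    space: DeviationSpace,
    data: OmicsMatrix,
    design: GroupDesign,
    origin: str = "disease",
) -> pd.DataFrame:
    """Per-sample decomposition for every retained sample of the space.

    Columns: sample_id, group, s (signed restorative scalar, positive =
    toward baseline), restorative_mag, nonrestorative_mag.
    """
    sub = data.data.loc[list(space.retained_sample_ids), list(space.feature_ids)]
    coords = space.transform(sub).to_numpy()
    rows = [decompose(space, c, origin=origin) for c in coords]
    out = pd.DataFrame(rows, columns=["s", "restorative_mag", "nonrestorative_mag"])
    out.insert(0, "sample_id", space.retained_sample_ids)
    out.insert(1, "group", [design.group(s) for s in space.retained_sample_ids])
    return out


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and SD of s, ||v1|| and ||v2||."""
    agg = table.groupby("group", sort=False)[
        ["s", "restorative_mag", "nonrestorative_mag"]
    ].agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    return agg.reset_index()
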