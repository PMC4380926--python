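"""Detection of unfavorable (overshoot) treatment outcomes.

A marker manifests an unfavorable outcome of a treatment when two
conditions hold: (i) the untreated-disease group mean differs from the
baseline mean, defining the marker's disease direction; and (ii) the
treatment group's level lies even farther from baseline than the
untreated-disease level, in that same direction, significantly by a
one-sided pooled-variance t-test.  All tested (marker, treatment) pairs
form a single Benjamini-Hochberg family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroupDesign, OmicsMatrix, ValidationError
from .association import bh_adjust

logger = logging.getLogger("devindex")


def marker_direction(values: pd.Series, design: GroupDesign) -> str:
    """Disease direction of a marker: 'up' if the disease-group mean exceeds
    the baseline mean, 'down' if below, 'none' if exactly equal."""
    base = design.samples_of(design.baseline_group, within=list(values.index))
    dis = design.samples_of(design.disease_group, within=list(values.index))
    mb = values.loc[base].mean(skipna=True)
    md = values.loc[dis].mean(skipna=True)
    if np.isnan(mb) or np.isnan(md):
        raise ValidationError("marker all-missing in baseline or disease group")
    if md > mb:
        return "up"
    if md < mb:
        return "down"
    return "none"


def one_sided_overshoot_test(treatment, disease, direction: str) -> tuple[float, float]:
    """Pooled-variance t of treatment vs untreated disease; one-sided p in
    the overshoot direction (upper tail if direction='up')."""
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    x = np.asarray(treatment, dtype=float)
    y = np.asarray(disease, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs >= 2 non-missing values")
    n1, n2 = x.size, y.size
    md = x.mean() - y.mean()
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if md == 0.0:
            logger.warning("overshoot test degenerate: both groups constant and equal")
            return 0.0, 0.5
        t = float(np.sign(md) * np.inf)
    else:
        t = float(md / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    df = n1 + n2 - 2
    p = stats.t.sf(t, df) if direction == "up" else stats.t.cdf(t, df)
    return t, float(p)


def detect_unfavorable(
    markers: OmicsMatrix,
    design: GroupDesign,
    alpha: float = 0.05,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Flag (marker, treatment) pairs that overshoot past the disease state.

    Tests every marker with a nonzero disease direction against every
    intervention group (default: all non-baseline, non-disease groups);
    BH-adjusts across the whole family at ``alpha``.  Returns one row per
    test with group means, t, one-sided p, adjusted p and the flag.
    """
    design.check_covers(markers)
    tested_groups = list(groups) if groups is not None else list(design.intervention_groups)
    if not tested_groups:
        raise ValidationError("no intervention groups to test")
    base = design.samples_of(design.baseline_group, within=markers.sample_ids)
    dis = design.samples_of(design.disease_group, within=markers.sample_ids)
    rows = []
    for marker in markers.feature_ids:
        col = markers.data[marker]
        direction = marker_direction(col, design)
        if direction == "none":
            logger.info("marker %s: equal group means, skipped", marker)
            continue
        disease_vals = col.loc[dis]
        for grp in tested_groups:
            members = design.samples_of(grp, within=markers.sample_ids)
            vals = col.loc[members].dropna()
            if len(vals) < 2:
                logger.info("marker %s, group %s: < 2 values, skipped", marker, grp)
                continue
            t, p = one_sided_overshoot_test(vals, disease_vals, direction)
            rows.append(
                {
                    "marker": marker,
                    "group": grp,
                    "direction": direction,
                    "t": t,
                    "p": p,
                    "mean_baseline": col.loc[base].mean(skipna=True),
                    "mean_disease": disease_vals.mean(skipna=True),
                    "mean_treatment": vals.mean(),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(p_adj=[], flagged=[])
    p_adj, reject = bh_adjust(out["p"].to_numpy(), alpha=alpha)
    out["p_adj"] = p_adj
    # a rejection implies the treatment mean lies beyond the disease mean in
    # the disease direction (one-sided p < 0.5); asserted for safety
    beyond = np.where(
        out["direction"] == "up",
        out["mean_treatment"] > out["mean_disease"],
        out["mean_treatment"] < out["mean_disease"],
    )
    out["flagged"] = reject & beyond
    logger.info(
        "unfavorable scan: %d tests (%d markers x %d groups families), %d flagged",
        len(out), out["marker"].nunique(), len(tested_groups), int(out["flagged"].sum()),
    )
    return out
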