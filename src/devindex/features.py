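"""Selection of the top differentially expressed features.

Features are ranked by the p-value of an ordinary pooled-variance
two-sample t-test between the disease and baseline groups; the top N
(default 200) define the axes of a tissue's deviation space.  Only
baseline and disease samples enter the ranking, so adding or removing
intervention samples cannot change the selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroupDesign, OmicsMatrix, ValidationError

logger = logging.getLogger("devindex")


@dataclass(frozen=True)
class FeatureSet:
    """Ranked differential features with their test statistics.

    ``table`` has columns feature_id, t, p, mean_diff (disease - baseline),
    rank; sorted ascending by p with deterministic tie-breaking (larger
    |mean_diff| first, then lexicographic feature ID).
    """

    table: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    def __len__(self) -> int:
        return len(self.table)


def two_sample_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test; returns (t, two-sided p).

    df = n1 + n2 - 2.  Degenerate cases: both groups constant and equal
    -> (0, 1) with a warning; zero pooled variance with unequal means ->
    (+/-inf, 0) with a warning (maximally separating feature).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs >= 2 values for a t-test")
    n1, n2 = x.size, y.size
    md = x.mean() - y.mean()
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if md == 0.0:
            logger.warning("t-test degenerate: both groups constant and equal")
            return 0.0, 1.0
        logger.warning("t-test degenerate: zero pooled variance, unequal means")
        return float(np.sign(md) * np.inf), 0.0
    t = md / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def _t_columns(x_mat: np.ndarray, y_mat: np.ndarray):
    """Vectorized pooled t over matrix columns (x = disease, y = baseline).

    Returns (t, p, mean_diff, degenerate_equal) arrays; degenerate_equal
    marks columns constant-and-equal in both groups (ineligible).
    """
    n1, n2 = x_mat.shape[0], y_mat.shape[0]
    md = x_mat.mean(axis=0) - y_mat.mean(axis=0)
    sp2 = ((n1 - 1) * x_mat.var(axis=0, ddof=1) + (n2 - 1) * y_mat.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    zero = sp2 == 0.0
    degenerate_equal = zero & (md == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[degenerate_equal] = 0.0
    sep = zero & ~degenerate_equal
    t[sep] = np.sign(md[sep]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), n1 + n2 - 2)
    p[zero & ~degenerate_equal] = 0.0
    return t, p, md, degenerate_equal


def select_top_features(expr: OmicsMatrix, design: GroupDesign, n_top: int) -> FeatureSet:
    """Rank all eligible features by baseline-vs-disease t-test p-value and
    return the first ``min(n_top, eligible)``.

    Eligibility excludes features constant and equal in both groups.  A
    zero-pooled-variance feature with unequal means ranks first (p = 0)
    with a warning.
    """
    if n_top <= 0:
        raise ValidationError("n_top must be positive")
    base = design.samples_of(design.baseline_group, within=expr.sample_ids)
    dis = design.samples_of(design.disease_group, within=expr.sample_ids)
    if len(base) < 2 or len(dis) < 2:
        raise ValidationError("need >= 2 baseline and >= 2 disease samples")
    x = expr.data.loc[dis].to_numpy(dtype=float)
    y = expr.data.loc[base].to_numpy(dtype=float)
    t, p, md, degenerate = _t_columns(x, y)
    if degenerate.any():
        for fid in np.asarray(expr.feature_ids)[degenerate]:
            logger.info("excluding feature %s: constant and equal in both groups", fid)
    n_inf = int(np.isinf(t[~degenerate]).sum())
    if n_inf:
        logger.warning("%d feature(s) with zero pooled variance, unequal means (p=0)", n_inf)
    tab = pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "t": t,
            "p": p,
            "mean_diff": md,
            "_absmd": np.abs(md),
        }
    ).loc[~degenerate]
    if tab.empty:
        raise ValidationError("no eligible features")
    tab = tab.sort_values(
        ["p", "_absmd", "feature_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_absmd")
    tab = tab.head(min(n_top, len(tab))).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    logger.info(
        "selected %d of %d features (n_top=%d, baseline n=%d, disease n=%d)",
        len(tab), expr.shape[1], n_top, len(base), len(dis),
    )
    return FeatureSet(tab)
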