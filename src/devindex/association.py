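"""Cross-layer correlation of deviation indices with FDR control.

Correlates molecular deviation indices (TDI per tissue, MDI) with
physiological ones (GPDI, per-marker PDI) on pairwise-complete samples.
The TDI-PDI analysis forms one Benjamini-Hochberg family over all
tissue x marker pairs; headline index-index correlations are reported
with both Pearson and Spearman coefficients.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError


def correlate(x, y, method: str = "pearson", exact: bool = False) -> tuple[float, float, int]:
    """Correlation of two index vectors on pairwise-complete entries.

    Returns (rho, two-sided p, n).  Pearson p comes from the t
    approximation with df = n - 2; Spearman uses mid-ranks for ties with
    the same t approximation, or an exact permutation p when
    ``exact=True`` (intended for n < 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("index vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 pairwise-complete samples, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("correlation undefined for a constant vector")
    if method == "pearson":
        rho, p = stats.pearsonr(x, y)
    elif method == "spearman":
        if exact:
            return _spearman_exact(x, y)
        rho, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(rho), float(p), n


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Exact permutation p for Spearman's rho (enumerates all n! orderings)."""
    n = x.size
    if n > 8:
        raise ValidationError("exact Spearman p only supported for n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total, n


def bh_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values in input order, reject flags at ``alpha``).
    Adjusted p_(k) = min over j >= k of min(1, m p_(j) / j) on the sorted
    scale; reject iff adjusted p <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def index_correlations(
    indices: dict[str, pd.DataFrame],
    pairs: list[tuple[str, str]],
    methods: tuple[str, ...] = ("pearson", "spearman"),
) -> pd.DataFrame:
    """Headline correlations between named index tables.

    ``indices`` maps a label (e.g. ``TDI-liver``, ``GPDI``) to an index
    table with sample_id and index columns; each requested pair is joined
    on sample_id (pairwise-complete) and correlated with every method.
    """
    rows = []
    for a, b in pairs:
        sa = indices[a].set_index("sample_id")["index"]
        sb = indices[b].set_index("sample_id")["index"]
        shared = sa.index.intersection(sb.index)
        for method in methods:
            rho, p, n = correlate(sa.loc[shared], sb.loc[shared], method=method)
            rows.append({"pair": f"{a}~{b}", "method": method, "rho": rho, "p": p, "n": n})
    return pd.DataFrame(rows)


def tdi_pdi_matrix(
    tdis: dict[str, pd.DataFrame],
    pdi: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each tissue's TDI against each marker's PDI.

    ``tdis`` maps tissue name to a TDI table; ``pdi`` is the wide
    per-sample x per-marker PDI table.  All tissue x marker tests form a
    single BH family at ``alpha``.  The output is sorted by the tissue
    whose TDI correlates more strongly with the marker (the tissue-split
    ordering of the published marker panel figure), then by rho.
    """
    rows = []
    for tissue, table in tdis.items():
        tdi = table.set_index("sample_id")["index"]
        for marker in pdi.columns:
            shared = tdi.index.intersection(pdi.index)
            rho, p, n = correlate(tdi.loc[shared], pdi.loc[shared, marker], method="spearman")
            rows.append(
                {"tissue": tissue, "marker": marker, "method": "spearman",
                 "rho": rho, "p": p, "n": n}
            )
    out = pd.DataFrame(rows)
    p_adj, reject = bh_adjust(out["p"].to_numpy(), alpha=alpha)
    out["p_adj"] = p_adj
    out["significant"] = reject
    # order markers by which tissue correlates more strongly
    best = out.loc[out.groupby("marker")["rho"].idxmax(), ["marker", "tissue"]]
    best_of = dict(zip(best["marker"], best["tissue"]))
    out["preferred_tissue"] = out["marker"].map(best_of)
    return out.sort_values(
        ["preferred_tissue", "marker", "tissue"], kind="mergesort"
    ).reset_index(drop=True)
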