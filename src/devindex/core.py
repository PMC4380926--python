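"""Core containers, I/O and configuration for the deviation-index pipeline.

The pipeline consumes already-normalized data: a log2-scale expression
matrix per tissue, a physiological marker table and (optionally) a
metabolite table, all samples-in-rows, plus a sample annotation assigning
each animal to an experimental group.  Raw-format preprocessing (microarray
background correction, quantile normalization) is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("devindex")

MATRIX_KINDS = ("expression", "physiology", "metabolome")

#: Cell contents treated as missing (case-insensitive).  Anything else that
#: fails numeric parsing is an error, never a silent NaN.
MISSING_TOKENS = frozenset({"", "na", "nan"})


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate IDs, missing data
    where completeness is required, unknown group, ...)."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries row/column coordinates."""


@dataclass(frozen=True)
class OmicsMatrix:
    """A samples x features numeric table with IDs.

    ``data`` is a float DataFrame indexed by sample ID with feature-ID
    columns.  Expression matrices must be complete; physiology and
    metabolome matrices may contain NaN (missing) entries.
    """

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("matrix must have at least one sample and one feature")
        for axis, name in ((self.data.index, "sample"), (self.data.columns, "feature")):
            dup = axis[axis.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {name} ID {dup[0]!r}")
        if self.kind == "expression" and self.data.isna().any().any():
            rows = self.data.index[self.data.isna().any(axis=1)]
            raise ValidationError(
                f"expression matrix contains missing values (e.g. sample {rows[0]!r})"
            )

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise ValidationError(f"features not in matrix: {missing[:5]}")
        return OmicsMatrix(self.data.loc[:, list(feature_ids)], self.kind)

    def select_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.data.loc[list(sample_ids)], self.kind)

    def drop_incomplete_samples(self) -> "OmicsMatrix":
        """Drop samples with any missing value, logging each exclusion."""
        keep = ~self.data.isna().any(axis=1)
        for sid in self.data.index[~keep]:
            logger.info("excluding sample %s: missing value(s)", sid)
        if not keep.any():
            raise ValidationError("all samples have missing values")
        return OmicsMatrix(self.data.loc[keep], self.kind)

    def drop_incomplete_features(self) -> "OmicsMatrix":
        """Drop features with any missing value, logging each exclusion."""
        keep = ~self.data.isna().any(axis=0)
        for fid in self.data.columns[~keep]:
            logger.info("excluding feature %s: missing value(s)", fid)
        if not keep.any():
            raise ValidationError("all features have missing values")
        return OmicsMatrix(self.data.loc[:, keep], self.kind)


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to experimental groups.

    ``baseline_group`` plays the healthy-reference role (the LFD group in
    the emulated design) and ``disease_group`` the untreated-disease role
    (16-week HFD).  ``intervention_groups`` are every other group, in a
    stable order.
    """

    group_of: Mapping[str, str]
    baseline_group: str
    disease_group: str
    intervention_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.baseline_group == self.disease_group:
            raise ValidationError("baseline and disease groups must differ")
        for g, role in ((self.baseline_group, "baseline"), (self.disease_group, "disease")):
            if sum(1 for v in self.group_of.values() if v == g) < 2:
                raise ValidationError(f"{role} group {g!r} needs >= 2 samples")
        if not self.intervention_groups:
            seen: list[str] = []
            for g in self.group_of.values():
                if g not in (self.baseline_group, self.disease_group) and g not in seen:
                    seen.append(g)
            object.__setattr__(self, "intervention_groups", tuple(seen))

    def group(self, sample_id: str) -> str:
        try:
            return self.group_of[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} has no group assignment") from None

    def samples_of(self, group: str, within: Sequence[str] | None = None) -> list[str]:
        pool = within if within is not None else list(self.group_of)
        return [s for s in pool if self.group_of.get(s) == group]

    def groups_in(self, sample_ids: Sequence[str]) -> pd.Series:
        """Group label per sample, raising if any sample is unassigned."""
        return pd.Series([self.group(s) for s in sample_ids], index=list(sample_ids), name="group")

    def check_covers(self, matrix: OmicsMatrix) -> None:
        for s in matrix.sample_ids:
            self.group(s)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable settings of the analysis.

    Defaults reproduce the published settings: top N = 200 features for
    each expression space and a Benjamini-Hochberg FDR level of 5%.
    """

    n_top_features: int = 200
    weighting_mode: str = "fisher"  # or "equal"
    weight_exponent: float = 1.0
    fdr_alpha: float = 0.05
    correlation_method: str = "pearson"
    decomposition_origin: str = "disease"  # or "grand_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_top_features <= 0:
            raise ValidationError("n_top_features must be positive")
        if self.weighting_mode not in ("fisher", "equal"):
            raise ValidationError(f"unknown weighting_mode {self.weighting_mode!r}")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError(f"unknown correlation_method {self.correlation_method!r}")
        if self.decomposition_origin not in ("disease", "grand_mean"):
            raise ValidationError(f"unknown decomposition_origin {self.decomposition_origin!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, kind: str, transpose: bool = False) -> OmicsMatrix:
    """Read a TSV/CSV matrix: one header row of feature IDs, first column
    of sample IDs.  ``transpose=True`` accepts features-in-rows dumps.

    Empty cells, "NA" and "NaN" (case-insensitive) denote missing values;
    any other non-numeric cell raises :class:`ParseError` with its
    coordinates.  Expression matrices must be complete.
    """
    path = Path(path)
    # pandas mangles duplicate header names; check them verbatim first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    dup = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dup):
        raise ValidationError(f"{path.name}: duplicate feature ID {dup[0]!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_missing = cells.str.lower().isin(MISSING_TOKENS)
        numeric = pd.to_numeric(cells.where(~is_missing), errors="coerce")
        bad = numeric.isna() & ~is_missing
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"{path.name}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{cells[bad].iloc[0]!r}"
            )
        parsed[col] = numeric
    if transpose:
        parsed = parsed.T
    m = OmicsMatrix(parsed, kind)
    logger.info("read %s matrix %s: %d samples x %d features", kind, path.name, *m.shape)
    return m


def read_design(
    path: str | Path,
    baseline_group: str,
    disease_group: str,
    intervention_groups: Sequence[str] | None = None,
) -> GroupDesign:
    """Read a sample annotation CSV/TSV with columns ``sample_id,group``."""
    path = Path(path)
    tab = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(tab.columns):
        raise ValidationError(f"{path.name}: annotation needs columns {sorted(required)}")
    dup = tab["sample_id"][tab["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path.name}: duplicate sample ID {dup.iloc[0]!r}")
    return GroupDesign(
        group_of=dict(zip(tab["sample_id"], tab["group"])),
        baseline_group=baseline_group,
        disease_group=disease_group,
        intervention_groups=tuple(intervention_groups or ()),
    )


def write_table(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as TSV.  Values round-trip through
    :func:`read_matrix` to <= 1e-12 relative error (full float repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    write_table(matrix.data, path)
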