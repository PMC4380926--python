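"""Synthetic multi-arm dyslipidemia-style study generator.

Emulates the structure of the motivating experiment: 14 groups (healthy
baseline LFD, a 9-week disease time point, untreated disease, a dietary
intervention and 10 drug arms) of 8 animals each with liver expression;
adipose expression in a 7-group subset; 26 physiological markers and a
liver-coupled metabolite panel measured in all animals.

The generative model couples every layer through a latent disease load.
Each group g has a planted load l_g in [0, 1] (0 = healthy baseline,
1 = untreated disease); animal i realizes a per-tissue load
l_i,t ~ Normal(l_g, animal_load_sd^2) clipped to [0, 1.5].  Expression in
tissue t is

    x_i = base + l_i,t * delta * d_t + beta_{g,t} * o_{g,t} + Normal(0, sigma^2 I)

with d_t a disease axis supported on the disease features and o_{g,t} a
per-group off-axis direction orthogonal to d_t inside that support
(off-axis shifts outside the disease-gene space would be invisible to a
space built from disease genes).  Axis and off-axis loadings are
normalized to unit root-mean-square over their support, so delta and
beta_g are per-feature effect scales in units of the noise SD: delta = 2
means a fully diseased animal's disease features shift by 2 sigma on
average, which is what makes them discoverable by the t-test ranking at
realistic group sizes.  Marker m of animal i is
a_m + c_m * l_i,tissue(m) + Normal(0, tau^2), with tissue(m) the marker's
coupled tissue (the mean load for 'both'); metabolites are generated like
liver-coupled markers.  Overshoot plants add a fixed shift, in the
marker's disease direction, to the named (marker, group) cells.

The generator is fully deterministic given the seed; the draw order is
fixed (per-tissue axes and baselines, then off-axis directions, then
marker/metabolite coefficient signs, then per-animal loads, then noise
layer by layer) so the same seed yields bit-identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GroupDesign, OmicsMatrix, ValidationError, write_table

DEFAULT_GROUPS = (
    "LFD", "HFD9", "HFD_untreated", "DLI",
    "metformin", "glibenclamide", "sitagliptin", "rosiglitazone", "pioglitazone",
    "fenofibrate", "T0901317", "atorvastatin", "salicylate", "rofecoxib",
)

#: Groups with adipose expression in the default design (7 of 14).
DEFAULT_ADIPOSE_GROUPS = (
    "LFD", "HFD9", "HFD_untreated", "DLI",
    "rosiglitazone", "pioglitazone", "T0901317",
)

#: Planted per-group disease loads: baseline 0, untreated disease 1, the
#: dietary intervention most restorative (0.1), drug arms spread between.
DEFAULT_LOADS = {
    "LFD": 0.0, "HFD9": 0.8, "HFD_untreated": 1.0, "DLI": 0.1,
    "metformin": 0.4, "glibenclamide": 0.6, "sitagliptin": 0.5,
    "rosiglitazone": 0.3, "pioglitazone": 0.35, "fenofibrate": 0.7,
    "T0901317": 0.85, "atorvastatin": 0.45, "salicylate": 0.65,
    "rofecoxib": 0.75,
}

#: Per-group off-axis magnitudes per tissue.  Fenofibrate and T0901317
#: carry large liver off-axis shifts, the thiazolidinediones
#: (rosiglitazone, pioglitazone) large adipose ones; the dietary arm the
#: smallest.  Values are distinct so rank recovery is well defined.
DEFAULT_OFF_AXIS = {
    "liver": {
        "LFD": 0.0, "HFD9": 0.0, "HFD_untreated": 0.0, "DLI": 0.1,
        "metformin": 0.4, "glibenclamide": 0.5, "sitagliptin": 0.6,
        "rosiglitazone": 0.7, "pioglitazone": 0.8, "fenofibrate": 2.5,
        "T0901317": 3.0, "atorvastatin": 0.9, "salicylate": 0.3,
        "rofecoxib": 0.2,
    },
    "adipose": {
        "LFD": 0.0, "HFD9": 0.0, "HFD_untreated": 0.0, "DLI": 0.1,
        "metformin": 0.3, "glibenclamide": 0.35, "sitagliptin": 0.45,
        "rosiglitazone": 2.5, "pioglitazone": 3.0, "fenofibrate": 0.4,
        "T0901317": 0.5, "atorvastatin": 0.55, "salicylate": 0.6,
        "rofecoxib": 0.25,
    },
}

#: 26-marker panel: 10 adipose-coupled, 10 liver-coupled, 6 coupled to both.
DEFAULT_MARKER_COUPLING = {
    # adipose-coupled
    "body_weight": "adipose", "total_WAT_weight": "adipose",
    "subcutaneous_WAT_weight": "adipose", "visceral_WAT_weight": "adipose",
    "ratio_visc_sub_WAT": "adipose", "plasma_leptin": "adipose",
    "adiponectin": "adipose", "resistin": "adipose",
    "plasma_glucose": "adipose", "albumin_creatinine_ratio": "adipose",
    # liver-coupled
    "plasma_cholesterol": "liver", "plasma_triglycerides": "liver",
    "liver_triglycerides": "liver", "liver_weight": "liver",
    "liver_cholesterol": "liver", "atherosclerotic_lesion_area": "liver",
    "plasma_ALT": "liver", "plasma_AST": "liver",
    "plasma_FFA": "liver", "plasma_LDL": "liver",
    # coupled to both tissues
    "plasma_insulin": "both", "HOMA_IR": "both", "plasma_HDL": "both",
    "plasma_CRP": "both", "plasma_IL6": "both", "heart_weight": "both",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study; defaults emulate the real design."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    baseline_group: str = "LFD"
    disease_group: str = "HFD_untreated"
    n_per_group: int = 8
    tissues: tuple[str, ...] = ("liver", "adipose")
    adipose_groups: tuple[str, ...] = DEFAULT_ADIPOSE_GROUPS
    n_features: int = 1000
    n_disease_features: int = 200
    effect_size: float = 2.0       # delta: axis loading scale (log2 units)
    noise_sd: float = 1.0          # sigma: expression noise
    animal_load_sd: float = 0.1
    load_clip: tuple[float, float] = (0.0, 1.5)
    disease_load: dict = field(default_factory=lambda: dict(DEFAULT_LOADS))
    off_axis: dict = field(default_factory=lambda: {t: dict(v) for t, v in DEFAULT_OFF_AXIS.items()})
    marker_coupling: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_COUPLING))
    marker_effect: float = 2.0     # |c_m|
    marker_noise_sd: float = 0.3   # tau
    marker_baseline: float = 10.0  # a_m
    n_metabolites: int = 168
    metabolite_effect: float = 2.0
    metabolite_noise_sd: float = 0.3
    overshoot_plants: tuple = ()   # (marker, group, shift) triples
    marker_missing: tuple = ()     # (sample_id, marker) cells set missing
    metabolite_missing: tuple = ()
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_disease_features > self.n_features:
            raise ValidationError("n_disease_features cannot exceed n_features")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        for g in (self.baseline_group, self.disease_group):
            if g not in self.groups:
                raise ValidationError(f"group {g!r} not in groups")
        missing = [g for g in self.groups if g not in self.disease_load]
        if missing:
            raise ValidationError(f"disease_load missing for {missing}")
        if self.disease_load[self.baseline_group] != 0.0:
            raise ValidationError("baseline group load must be 0")
        if self.disease_load[self.disease_group] != 1.0:
            raise ValidationError("disease group load must be 1")
        if any(b < 0 for t in self.off_axis.values() for b in t.values()):
            raise ValidationError("off-axis magnitudes must be >= 0")
        if any(b > 0 for t in self.off_axis.values() for b in t.values()) and self.n_disease_features < 2:
            raise ValidationError("off-axis direction needs >= 2 disease features")

    @property
    def n_markers(self) -> int:
        return len(self.marker_coupling)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def nominal_marker_sd(config: SyntheticConfig) -> float:
    """Nominal within-group SD of a marker: measurement noise plus the
    load-jitter contribution through the coupling coefficient."""
    return float(
        np.sqrt(config.marker_noise_sd ** 2 + (config.marker_effect * config.animal_load_sd) ** 2)
    )


@dataclass(frozen=True)
class GroundTruth:
    """Realized latent state of a generated study."""

    group_loads: dict                 # group -> planted l_g
    animal_loads: pd.DataFrame        # sample x tissue realized loads
    axes: dict                        # tissue -> unit disease axis (n_features,)
    off_axis_dirs: dict               # tissue -> group -> unit direction
    off_axis_mags: dict               # tissue -> group -> beta
    marker_signs: pd.Series           # marker -> sign of c_m
    overshoot_plants: tuple


@dataclass(frozen=True)
class SyntheticStudy:
    expression: dict                  # tissue -> OmicsMatrix
    markers: OmicsMatrix
    metabolites: OmicsMatrix
    design: GroupDesign
    truth: GroundTruth


def default_study_config(seed: int = 42) -> SyntheticConfig:
    """The default emulated study: 14 groups x 8 animals with liver
    expression (112 samples), adipose expression in 7 groups, 26 markers,
    168 metabolites, two planted overshoot pairs (the thiazolidinedione-
    adiponectin and T0901317-cholesterol patterns) at 5 nominal
    within-group SDs, and a few planted missing cells exercising the
    GPDI/MDI exclusion rules."""
    cfg = SyntheticConfig(seed=seed)

    # plant shifts sized so the treated group lands 5 nominal within-group
    # SDs beyond the untreated-disease mean: the arm sits at load l_g, so
    # the shift must first cover the gap c(1 - l_g) up to the disease state
    def plant_shift(group: str) -> float:
        gap = cfg.marker_effect * (1.0 - cfg.disease_load[group])
        return gap + 5.0 * nominal_marker_sd(cfg)

    return cfg.replace(
        overshoot_plants=(
            ("adiponectin", "pioglitazone", plant_shift("pioglitazone")),
            ("plasma_cholesterol", "T0901317", plant_shift("T0901317")),
        ),
        marker_missing=(
            ("metformin_03", "plasma_CRP"),
            ("salicylate_05", "plasma_IL6"),
            ("rofecoxib_02", "albumin_creatinine_ratio"),
        ),
        metabolite_missing=(
            ("glibenclamide_04", "metabolite_0007"),
            ("HFD9_06", "metabolite_0131"),
        ),
    )


def _unit_rms(v: np.ndarray, support_size: int) -> np.ndarray:
    """Normalize so the loadings have unit RMS over their support."""
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValidationError("degenerate zero vector")
    return v * (np.sqrt(support_size) / n)


def generate(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full synthetic study from the config (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    groups = config.groups
    n = config.n_per_group
    sample_ids = [f"{g}_{i + 1:02d}" for g in groups for i in range(n)]
    group_of = {s: g for s, g in zip(sample_ids, np.repeat(groups, n))}
    design = GroupDesign(
        group_of=group_of,
        baseline_group=config.baseline_group,
        disease_group=config.disease_group,
    )

    # 1. per-tissue axes, feature baselines and per-group off-axis directions
    support = np.arange(config.n_disease_features)
    axes: dict[str, np.ndarray] = {}
    bases: dict[str, np.ndarray] = {}
    off_dirs: dict[str, dict[str, np.ndarray]] = {}
    for tissue in config.tissues:
        d = np.zeros(config.n_features)
        d[support] = rng.standard_normal(config.n_disease_features)
        d = _unit_rms(d, config.n_disease_features)
        axes[tissue] = d
        bases[tissue] = rng.normal(7.0, 1.0, config.n_features)
        d_hat = d / np.linalg.norm(d)
        dirs = {}
        for g in groups:
            o = np.zeros(config.n_features)
            o[support] = rng.standard_normal(config.n_disease_features)
            o -= (o @ d_hat) * d_hat
            dirs[g] = _unit_rms(o, config.n_disease_features)
        off_dirs[tissue] = dirs

    # 2. marker and metabolite coefficient signs
    marker_names = list(config.marker_coupling)
    marker_signs = pd.Series(
        rng.choice([-1.0, 1.0], size=len(marker_names)), index=marker_names
    )
    met_names = [f"metabolite_{i + 1:04d}" for i in range(config.n_metabolites)]
    met_signs = rng.choice([-1.0, 1.0], size=config.n_metabolites)

    # 3. per-animal per-tissue realized loads
    planted = np.array([config.disease_load[group_of[s]] for s in sample_ids])
    lo, hi = config.load_clip
    loads = np.clip(
        rng.normal(planted[:, None], config.animal_load_sd, (len(sample_ids), len(config.tissues))),
        lo, hi,
    )
    animal_loads = pd.DataFrame(loads, index=sample_ids, columns=list(config.tissues))

    # 4. expression per tissue (noise drawn tissue by tissue, in tissue order)
    expression: dict[str, OmicsMatrix] = {}
    feature_ids = [f"probe_{i + 1:05d}" for i in range(config.n_features)]
    for tissue in config.tissues:
        rows = (
            sample_ids
            if tissue != "adipose" or not config.adipose_groups
            else [s for s in sample_ids if group_of[s] in config.adipose_groups]
        )
        li = animal_loads.loc[rows, tissue].to_numpy()
        betas = np.array([config.off_axis[tissue][group_of[s]] for s in rows])
        odirs = np.stack([off_dirs[tissue][group_of[s]] for s in rows])
        x = (
            bases[tissue][None, :]
            + li[:, None] * config.effect_size * axes[tissue][None, :]
            + betas[:, None] * odirs
            + rng.normal(0.0, config.noise_sd, (len(rows), config.n_features))
        )
        expression[tissue] = OmicsMatrix(
            pd.DataFrame(x, index=rows, columns=feature_ids), "expression"
        )

    # 5. markers: a_m + c_m * load through the coupled tissue + noise
    marker_vals = np.empty((len(sample_ids), len(marker_names)))
    for j, m in enumerate(marker_names):
        coup = config.marker_coupling[m]
        if coup == "both":
            lm = animal_loads.mean(axis=1).to_numpy()
        else:
            lm = animal_loads[coup].to_numpy()
        c = marker_signs[m] * config.marker_effect
        marker_vals[:, j] = config.marker_baseline + c * lm
    marker_vals += rng.normal(0.0, config.marker_noise_sd, marker_vals.shape)
    markers_df = pd.DataFrame(marker_vals, index=sample_ids, columns=marker_names)

    # 6. metabolites, generated like liver-coupled markers
    ll = animal_loads["liver"].to_numpy() if "liver" in animal_loads else animal_loads.iloc[:, 0].to_numpy()
    met_vals = (
        config.marker_baseline
        + np.outer(ll, met_signs * config.metabolite_effect)
        + rng.normal(0.0, config.metabolite_noise_sd, (len(sample_ids), config.n_metabolites))
    )
    met_df = pd.DataFrame(met_vals, index=sample_ids, columns=met_names)

    # 7. overshoot plants: shift in the marker's disease direction
    for marker, group, shift in config.overshoot_plants:
        if marker not in markers_df.columns or group not in groups:
            raise ValidationError(f"unknown overshoot plant ({marker!r}, {group!r})")
        members = [s for s in sample_ids if group_of[s] == group]
        markers_df.loc[members, marker] += marker_signs[marker] * shift

    # 8. planted missing cells
    for df, cells, what in (
        (markers_df, config.marker_missing, "marker"),
        (met_df, config.metabolite_missing, "metabolite"),
    ):
        for sid, m in cells:
            if sid not in df.index or m not in df.columns:
                raise ValidationError(f"unknown {what} missing cell ({sid!r}, {m!r})")
            df.loc[sid, m] = np.nan

    truth = GroundTruth(
        group_loads=dict(config.disease_load),
        animal_loads=animal_loads,
        axes=axes,
        off_axis_dirs=off_dirs,
        off_axis_mags={t: dict(v) for t, v in config.off_axis.items()},
        marker_signs=marker_signs,
        overshoot_plants=tuple(config.overshoot_plants),
    )
    return SyntheticStudy(
        expression=expression,
        markers=OmicsMatrix(markers_df, "physiology"),
        metabolites=OmicsMatrix(met_df, "metabolome"),
        design=design,
        truth=truth,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study matrices, annotation CSV and ground-truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tissue, mat in study.expression.items():
        paths[f"expression_{tissue}"] = p = out / f"expression_{tissue}.tsv"
        write_table(mat.data, p)
    paths["markers"] = out / "markers.tsv"
    write_table(study.markers.data, paths["markers"])
    paths["metabolites"] = out / "metabolites.tsv"
    write_table(study.metabolites.data, paths["metabolites"])
    ann = pd.DataFrame(
        {"sample_id": list(study.design.group_of), "group": list(study.design.group_of.values())}
    )
    paths["annotation"] = out / "annotation.csv"
    ann.to_csv(paths["annotation"], index=False)
    paths["truth_loads"] = out / "truth_animal_loads.tsv"
    write_table(study.truth.animal_loads, paths["truth_loads"])
    return paths
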