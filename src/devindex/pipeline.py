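"""End-to-end orchestration: feature selection -> deviation spaces ->
indices -> decomposition -> cross-layer correlations -> unfavorable scan."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import GroupDesign, OmicsMatrix, PipelineConfig, ValidationError, write_table
from .features import FeatureSet, select_top_features
from .space import DeviationSpace, build_deviation_space, index_table, pdi_table
from .decomposition import decomposition_table, group_summary
from .association import index_correlations, tdi_pdi_matrix
from .unfavorable import detect_unfavorable
from .simulate import SyntheticStudy, default_study_config, generate

logger = logging.getLogger("devindex")


@dataclass
class StudyInputs:
    """The matrices and design a pipeline run consumes."""

    expression: dict  # tissue -> OmicsMatrix (complete, log2 scale)
    markers: OmicsMatrix
    design: GroupDesign
    metabolites: OmicsMatrix | None = None


@dataclass
class PipelineResult:
    """Everything a run computes, ready to write or inspect."""

    config: PipelineConfig
    feature_sets: dict = field(default_factory=dict)      # tissue -> FeatureSet
    spaces: dict = field(default_factory=dict)            # name -> DeviationSpace
    indices: dict = field(default_factory=dict)           # label -> index table
    pdi: pd.DataFrame | None = None
    decomposition: dict = field(default_factory=dict)     # tissue -> per-sample table
    decomposition_groups: dict = field(default_factory=dict)
    correlations: pd.DataFrame | None = None
    tdi_pdi: pd.DataFrame | None = None
    unfavorable: pd.DataFrame | None = None

    def headline(self) -> dict:
        """Headline numbers: index-index Pearson correlations, per-group
        non-restorative means, flagged unfavorable pairs."""
        out: dict = {}
        if self.correlations is not None:
            for _, r in self.correlations.iterrows():
                out[f"{r['method']}_{r['pair']}"] = round(float(r["rho"]), 4)
        for tissue, tab in self.decomposition_groups.items():
            out[f"nonrestorative_mean_{tissue}"] = {
                g: round(float(v), 3)
                for g, v in zip(tab["group"], tab["nonrestorative_mag_mean"])
            }
        if self.unfavorable is not None and len(self.unfavorable):
            flagged = self.unfavorable.loc[self.unfavorable["flagged"]]
            out["unfavorable_flagged"] = [
                f"{m}:{g}" for m, g in zip(flagged["marker"], flagged["group"])
            ]
        if self.tdi_pdi is not None:
            out["n_significant_tdi_pdi"] = int(self.tdi_pdi["significant"].sum())
        return out


def analyze(inputs: StudyInputs, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    config = config or PipelineConfig()
    res = PipelineResult(config=config)
    design = inputs.design

    # expression layer: select features, build space, TDI, decomposition
    for tissue, expr in inputs.expression.items():
        fs = select_top_features(expr, design, config.n_top_features)
        res.feature_sets[tissue] = fs
        space = build_deviation_space(
            expr.select_features(fs.feature_ids),
            design,
            weighting_mode=config.weighting_mode,
            weight_exponent=config.weight_exponent,
            name=f"TDI-{tissue}",
        )
        res.spaces[f"TDI-{tissue}"] = space
        res.indices[f"TDI-{tissue}"] = index_table(space, expr, design, f"TDI-{tissue}")
        dec = decomposition_table(space, expr, design, origin=config.decomposition_origin)
        res.decomposition[tissue] = dec
        res.decomposition_groups[tissue] = group_summary(dec)

    # physiological layer: GPDI space (sample-complete rule) and PDIs
    gpdi_space = build_deviation_space(
        inputs.markers, design,
        weighting_mode=config.weighting_mode,
        weight_exponent=config.weight_exponent,
        name="GPDI",
    )
    res.spaces["GPDI"] = gpdi_space
    res.indices["GPDI"] = index_table(gpdi_space, inputs.markers, design, "GPDI")
    res.pdi = pdi_table(inputs.markers, design)

    # metabolome layer: incomplete metabolites excluded feature-wise
    pairs = [(f"TDI-{t}", "GPDI") for t in inputs.expression]
    if inputs.metabolites is not None:
        mets = inputs.metabolites.drop_incomplete_features()
        mdi_space = build_deviation_space(
            mets, design,
            weighting_mode=config.weighting_mode,
            weight_exponent=config.weight_exponent,
            name="MDI",
        )
        res.spaces["MDI"] = mdi_space
        res.indices["MDI"] = index_table(mdi_space, mets, design, "MDI")
        if "liver" in inputs.expression:
            pairs.append(("MDI", "TDI-liver"))
        pairs.append(("MDI", "GPDI"))

    # associations and the unfavorable scan
    res.correlations = index_correlations(res.indices, pairs)
    tdis = {t: res.indices[f"TDI-{t}"] for t in inputs.expression}
    res.tdi_pdi = tdi_pdi_matrix(tdis, res.pdi, alpha=config.fdr_alpha)
    res.unfavorable = detect_unfavorable(inputs.markers, design, alpha=config.fdr_alpha)
    return res


def simulate_inputs(seed: int = 42, sim_config=None) -> tuple[StudyInputs, SyntheticStudy]:
    """Generate the default synthetic study and wrap it as pipeline inputs."""
    study = generate(sim_config or default_study_config(seed=seed))
    return (
        StudyInputs(
            expression=study.expression,
            markers=study.markers,
            metabolites=study.metabolites,
            design=study.design,
        ),
        study,
    )


def write_result(res: PipelineResult, out_dir: str | Path) -> dict[str, str]:
    """Write every stage output as TSV plus a machine-readable report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name: str, table: pd.DataFrame, index: bool = False) -> None:
        p = out / f"{name}.tsv"
        write_table(table, p, index=index)
        paths[name] = str(p)

    for tissue, fs in res.feature_sets.items():
        _save(f"features_{tissue}", fs.table)
    for label, tab in res.indices.items():
        _save(label.lower().replace("-", "_"), tab)
    if res.pdi is not None:
        long = res.pdi.stack(future_stack=True).rename("pdi").reset_index()
        long.columns = ["sample_id", "marker", "pdi"]
        _save("pdi", long)
    for tissue, tab in res.decomposition.items():
        _save(f"decomposition_{tissue}", tab)
        _save(f"decomposition_groups_{tissue}", res.decomposition_groups[tissue])
    if res.correlations is not None:
        _save("correlations", res.correlations)
    if res.tdi_pdi is not None:
        _save("tdi_pdi", res.tdi_pdi)
    if res.unfavorable is not None:
        _save("unfavorable", res.unfavorable)
    for name, space in res.spaces.items():
        p = out / f"space_{name.lower().replace('-', '_')}.json"
        space.to_json(p)
        paths[f"space_{name}"] = str(p)

    report = {"outputs": paths, "seed": res.config.seed, "headline": res.headline()}
    (out / "report.json").write_text(json.dumps(report, indent=2))
    paths["report"] = str(out / "report.json")
    return paths


def run_pipeline(
    config: PipelineConfig | None = None,
    inputs: StudyInputs | None = None,
    simulate: bool = False,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """One-shot run: simulate (or take provided inputs), analyze, and
    optionally write all outputs."""
    config = config or PipelineConfig()
    if simulate:
        inputs, _ = simulate_inputs(seed=config.seed)
    if inputs is None:
        raise ValidationError("provide inputs or set simulate=True")
    res = analyze(inputs, config)
    if out_dir is not None:
        write_result(res, out_dir)
    return res
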