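"""Synthetic study generator: determinism, geometry and planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devindex import (
    ValidationError,
    default_study_config,
    generate,
    read_matrix,
    write_study,
)
from .conftest import scaled_study_config


@pytest.fixture(scope="module")
def study():
    return generate(scaled_study_config(seed=7))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = scaled_study_config(seed=11)
        a, b = generate(cfg), generate(cfg)
        for t in a.expression:
            pd.testing.assert_frame_equal(a.expression[t].data, b.expression[t].data)
        pd.testing.assert_frame_equal(a.markers.data, b.markers.data)
        pd.testing.assert_frame_equal(a.metabolites.data, b.metabolites.data)

    def test_different_seeds_differ(self):
        a = generate(scaled_study_config(seed=11))
        b = generate(scaled_study_config(seed=12))
        assert not np.allclose(a.expression["liver"].values, b.expression["liver"].values)


class TestDefaultDesign:
    def test_liver_covers_all_14_groups_of_8(self):
        cfg = default_study_config()
        study = generate(cfg.replace(n_features=50, n_disease_features=10, n_metabolites=5,
                                     metabolite_missing=()))
        assert study.expression["liver"].shape[0] == 112
        groups = study.design.groups_in(study.expression["liver"].sample_ids)
        assert groups.nunique() == 14
        assert (groups.value_counts() == 8).all()

    def test_adipose_restricted_to_configured_subset(self, study):
        cfg = scaled_study_config(seed=7)
        groups = study.design.groups_in(study.expression["adipose"].sample_ids)
        assert set(groups) == set(cfg.adipose_groups)
        assert study.expression["adipose"].shape[0] == 7 * 8

    def test_reference_group_loads(self, study):
        assert study.truth.group_loads["LFD"] == 0.0
        assert study.truth.group_loads["HFD_untreated"] == 1.0
        # the dietary intervention carries the lowest intervention load
        drug_loads = {g: l for g, l in study.truth.group_loads.items()
                      if g not in ("LFD", "HFD_untreated")}
        assert min(drug_loads, key=drug_loads.get) == "DLI"


class TestGeometry:
    def test_off_axis_orthogonal_to_disease_axis(self, study):
        for tissue, d in study.truth.axes.items():
            for g, o in study.truth.off_axis_dirs[tissue].items():
                assert abs(d @ o) / (np.linalg.norm(d) * np.linalg.norm(o)) < 1e-10

    def test_noise_free_positions_are_exact(self):
        cfg = scaled_study_config(seed=3)
        cfg = cfg.replace(
            noise_sd=0.0,
            animal_load_sd=0.0,
            off_axis={t: {g: 0.0 for g in v} for t, v in cfg.off_axis.items()},
        )
        study = generate(cfg)
        x = study.expression["liver"].values
        d = study.truth.axes["liver"]
        loads = study.truth.animal_loads["liver"].to_numpy()
        base = x[0] - loads[0] * cfg.effect_size * d  # LFD animal at load 0
        expected = base[None, :] + loads[:, None] * cfg.effect_size * d[None, :]
        np.testing.assert_allclose(x, expected, atol=1e-12)

    def test_realized_loads_track_planted_loads(self):
        """With planted group loads of variance ~0.077 and animal-level
        jitter of SD 0.1, the expected realized-vs-planted correlation is
        sqrt(V / (V + 0.01)) ~ 0.94."""
        study = generate(scaled_study_config(seed=42))
        planted = np.array(
            [study.truth.group_loads[study.design.group(s)]
             for s in study.truth.animal_loads.index]
        )
        r = stats.pearsonr(study.truth.animal_loads["liver"], planted).statistic
        assert r >= 0.9


class TestPlants:
    def test_overshoot_shifts_named_cells_in_disease_direction(self):
        cfg = scaled_study_config(seed=5)
        null = generate(cfg.replace(overshoot_plants=()))
        planted = generate(cfg)
        for marker, group, shift in cfg.overshoot_plants:
            members = [s for s in planted.markers.sample_ids
                       if planted.design.group(s) == group]
            delta = (planted.markers.data.loc[members, marker]
                     - null.markers.data.loc[members, marker])
            sign = planted.truth.marker_signs[marker]
            np.testing.assert_allclose(delta, sign * shift, atol=1e-12)

    def test_missing_only_where_planted(self, study):
        cfg = scaled_study_config(seed=7)
        na = study.markers.data.isna()
        assert int(na.sum().sum()) == len(cfg.marker_missing)
        for sid, marker in cfg.marker_missing:
            assert np.isnan(study.markers.data.loc[sid, marker])
        assert not study.metabolites.data.isna().any().any()  # none planted in scaled config

    def test_unknown_plant_rejected(self):
        cfg = scaled_study_config(seed=5).replace(
            overshoot_plants=(("no_such_marker", "DLI", 1.0),)
        )
        with pytest.raises(ValidationError, match="no_such_marker"):
            generate(cfg)

    def test_unknown_missing_cell_rejected(self):
        cfg = scaled_study_config(seed=5).replace(
            marker_missing=(("LFD_01", "no_such_marker"),)
        )
        with pytest.raises(ValidationError, match="no_such_marker"):
            generate(cfg)


class TestWriteStudy:
    def test_written_study_reads_back(self, study, tmp_path):
        paths = write_study(study, tmp_path)
        liver = read_matrix(paths["expression_liver"], "expression")
        np.testing.assert_allclose(liver.values, study.expression["liver"].values, rtol=1e-12)
        markers = read_matrix(paths["markers"], "physiology")
        assert markers.data.isna().sum().sum() == study.markers.data.isna().sum().sum()
        ann = pd.read_csv(paths["annotation"])
        assert set(ann.columns) == {"sample_id", "group"}
        assert len(ann) == 112
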