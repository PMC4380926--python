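"""Fisher scores, deviation-space construction and deviation indices."""

import logging

import numpy as np
import pandas as pd
import pytest

from devindex import (
    DeviationSpace,
    GroupDesign,
    OmicsMatrix,
    ValidationError,
    build_deviation_space,
    deviation_index,
    fisher_score,
    fisher_scores,
    index_table,
    pdi_table,
)


def brute_fisher(g1, g2):
    """Independent evaluation of the Fisher score formula."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    n1, n2 = len(g1), len(g2)
    mu = np.concatenate([g1, g2]).mean()
    num = n1 * (g1.mean() - mu) ** 2 + n2 * (g2.mean() - mu) ** 2
    den = n1 * g1.var(ddof=1) + n2 * g2.var(ddof=1)
    return num / den


def brute_weighted_distance(space, raw_row, raw_matrix, baseline_samples):
    """Fisher-weighted Euclidean distance to the baseline centroid computed
    directly in z-space, bypassing the rotation."""
    z = (raw_matrix - space.z_mean) / space.z_sd
    w = z * space.weights
    centroid = w[baseline_samples].mean(axis=0)
    zr = (raw_row - space.z_mean) / space.z_sd * space.weights
    return float(np.linalg.norm(zr - centroid))


def manual_space(weights, baseline_centroid, disease_centroid, p=None):
    """A hand-built space with identity rotation for closed-form checks."""
    p = p or len(weights)
    return DeviationSpace(
        name="manual",
        feature_ids=tuple(f"f{i}" for i in range(p)),
        z_mean=np.zeros(p),
        z_sd=np.ones(p),
        weights=np.asarray(weights, float),
        rotation=np.eye(p),
        grand_mean=np.zeros(p),
        baseline_centroid=np.asarray(baseline_centroid, float),
        disease_centroid=np.asarray(disease_centroid, float),
        retained_sample_ids=("a", "b"),
        baseline_group="base",
        disease_group="dis",
    )


class TestFisherScore:
    def test_hand_case(self):
        # mu = 2.5, numerator 13.5, denominator 6
        f = fisher_score([0, 1, 2, 3, 4, 5], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(2.25, abs=1e-15)

    def test_identical_means_give_zero(self):
        f = fisher_score([1, 2, 3, 3, 2, 1], ["a"] * 3 + ["b"] * 3)
        assert f == 0.0

    def test_scale_invariance(self, rng):
        x = rng.normal(size=10)
        labels = ["a"] * 5 + ["b"] * 5
        assert fisher_score(2 * x, labels) == pytest.approx(fisher_score(x, labels), rel=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            g1 = rng.normal(size=rng.integers(2, 15))
            g2 = rng.normal(size=rng.integers(2, 15))
            f = fisher_scores(g1[:, None], g2[:, None])[0]
            assert f == pytest.approx(brute_fisher(g1, g2), rel=1e-12)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValidationError):
            fisher_score([0, 0, 1, 1], ["a", "a", "b", "b"])


class TestBuildSpace:
    def _space_and_data(self, rng, n=30, p=20, mode="fisher"):
        samples = [f"s{i}" for i in range(n)]
        groups = {s: ("base" if i < 6 else "dis" if i < 12 else "trt") for i, s in enumerate(samples)}
        design = GroupDesign(groups, "base", "dis")
        x = rng.normal(size=(n, p))
        x[6:12, : p // 2] += 2.0  # disease shift on half the features
        mat = OmicsMatrix(pd.DataFrame(x, index=samples, columns=[f"f{j}" for j in range(p)]), "expression")
        return build_deviation_space(mat, design, weighting_mode=mode), mat, design

    def test_rotation_is_orthonormal(self, rng):
        space, _, _ = self._space_and_data(rng)
        r = space.rotation
        np.testing.assert_allclose(r.T @ r, np.eye(r.shape[0]), atol=1e-10)

    def test_baseline_centroid_matches_projected_mean(self, rng):
        space, mat, design = self._space_and_data(rng)
        coords = space.transform(mat)
        base = design.samples_of("base")
        np.testing.assert_allclose(
            coords.loc[base].mean(axis=0), space.baseline_centroid, atol=1e-10
        )

    def test_equal_mode_is_plain_z_isometry(self, rng):
        space, mat, _ = self._space_and_data(rng, mode="equal")
        assert np.all(space.weights == 1.0)
        z = (mat.values - space.z_mean) / space.z_sd
        coords = space.transform(mat).to_numpy()
        d_rot = np.linalg.norm(coords[0] - coords[1:], axis=1)
        d_z = np.linalg.norm(z[0] - z[1:], axis=1)
        np.testing.assert_allclose(d_rot, d_z, rtol=1e-8)

    def test_index_equals_brute_weighted_distance(self, rng):
        space, mat, design = self._space_and_data(rng, n=30, p=50)
        base_idx = [mat.sample_ids.index(s) for s in design.samples_of("base")]
        coords = space.transform(mat).to_numpy()
        idx = space.index_of(coords)
        for i in range(mat.shape[0]):
            brute = brute_weighted_distance(space, mat.values[i], mat.values, base_idx)
            assert idx[i] == pytest.approx(brute, rel=1e-8)

    def test_component_signs_do_not_matter(self, rng):
        space, mat, design = self._space_and_data(rng)
        signs = rng.choice([-1.0, 1.0], size=space.rotation.shape[1])
        flipped = DeviationSpace(
            **{
                **space.__dict__,
                "rotation": space.rotation * signs,
                "baseline_centroid": space.baseline_centroid * signs,
                "disease_centroid": space.disease_centroid * signs,
            }
        )
        t1 = index_table(space, mat, design, "x")["index"]
        t2 = index_table(flipped, mat, design, "x")["index"]
        np.testing.assert_allclose(t1, t2, rtol=1e-10)

    def test_affine_rescaling_of_raw_feature_is_absorbed(self, rng):
        space, mat, design = self._space_and_data(rng)
        scaled = mat.data.copy()
        scaled["f0"] = scaled["f0"] * 7.5 - 3.0
        space2 = build_deviation_space(OmicsMatrix(scaled, "expression"), design)
        t1 = index_table(space, mat, design, "x")["index"]
        t2 = index_table(space2, OmicsMatrix(scaled, "expression"), design, "x")["index"]
        np.testing.assert_allclose(t1, t2, rtol=1e-8)

    def test_zero_variance_feature_dropped(self, rng, toy_design):
        df = pd.DataFrame(
            rng.normal(size=(8, 3)), index=list(toy_design.group_of), columns=["a", "b", "c"]
        )
        df["b"] = 4.2
        space = build_deviation_space(OmicsMatrix(df, "expression"), toy_design)
        assert space.feature_ids == ("a", "c")

    def test_incomplete_samples_excluded(self, rng, toy_design):
        df = pd.DataFrame(
            rng.normal(size=(8, 3)), index=list(toy_design.group_of), columns=["a", "b", "c"]
        )
        df.loc["t1", "b"] = np.nan
        space = build_deviation_space(OmicsMatrix(df, "physiology"), toy_design)
        assert "t1" not in space.retained_sample_ids
        assert len(space.retained_sample_ids) == 7

    def test_json_round_trip(self, rng, tmp_path):
        space, mat, design = self._space_and_data(rng)
        p = tmp_path / "space.json"
        space.to_json(p)
        loaded = DeviationSpace.from_json(p)
        t1 = index_table(space, mat, design, "x")["index"]
        t2 = index_table(loaded, mat, design, "x")["index"]
        np.testing.assert_allclose(t1, t2, rtol=1e-12)


class TestDeviationIndex:
    def test_weighted_toy_distance(self):
        # z = (1, -1), weights (2, 1), baseline at origin -> sqrt(5)
        space = manual_space([2.0, 1.0], [0.0, 0.0], [1.0, 0.0])
        val = deviation_index(space, {"f0": 1.0, "f1": -1.0})
        assert val == pytest.approx(np.sqrt(5.0), abs=1e-12)

    def test_baseline_centroid_has_zero_index(self, rng):
        samples = [f"s{i}" for i in range(12)]
        design = GroupDesign(
            {s: ("base" if i < 5 else "dis") for i, s in enumerate(samples)}, "base", "dis"
        )
        mat = OmicsMatrix(
            pd.DataFrame(rng.normal(size=(12, 6)), index=samples,
                         columns=[f"f{j}" for j in range(6)]),
            "expression",
        )
        space = build_deviation_space(mat, design)
        coords = space.transform(mat)
        centroid = coords.loc[design.samples_of("base")].mean(axis=0).to_numpy()
        assert space.index_of(centroid)[0] == pytest.approx(0.0, abs=1e-10)

    def test_missing_feature_named_in_error(self):
        space = manual_space([1.0, 1.0], [0.0, 0.0], [1.0, 0.0])
        with pytest.raises(ValidationError, match="f1"):
            deviation_index(space, {"f0": 1.0})


class TestPDI:
    def test_hand_cases(self, toy_design):
        df = pd.DataFrame(
            {"m": [4.0, 5.0, 6.0, 7.0, 5.0, 9.0, 2.0, 5.0]}, index=list(toy_design.group_of)
        )
        pdi = pdi_table(OmicsMatrix(df, "physiology"), toy_design)
        assert pdi.loc["d1", "m"] == pytest.approx(2.0)  # |7 - 5|
        assert pdi.loc["d2", "m"] == pytest.approx(0.0)
        assert pdi.loc["t1", "m"] == pytest.approx(3.0)

    def test_z_scored_pdi_is_scaled_raw_pdi(self, rng, toy_design):
        df = pd.DataFrame(
            rng.normal(5, 2, size=(8, 3)), index=list(toy_design.group_of),
            columns=["m1", "m2", "m3"],
        )
        raw = pdi_table(OmicsMatrix(df, "physiology"), toy_design)
        sd = df.std(ddof=1)
        zdf = (df - df.mean()) / sd
        zed = pdi_table(OmicsMatrix(zdf, "physiology"), toy_design)
        np.testing.assert_allclose(zed, raw / sd, atol=1e-10)

    def test_missing_value_gives_missing_pdi_sample_kept(self, toy_design):
        df = pd.DataFrame(
            {"m1": [1.0] * 8, "m2": [2.0] * 8}, index=list(toy_design.group_of)
        )
        df.loc["t1", "m1"] = np.nan
        df.loc["b1", "m1"] = 4.0  # give m1 baseline variation
        pdi = pdi_table(OmicsMatrix(df, "physiology"), toy_design)
        assert np.isnan(pdi.loc["t1", "m1"])
        assert pdi.loc["t1", "m2"] == 0.0

    def test_marker_all_missing_in_baseline_warns(self, toy_design, caplog):
        df = pd.DataFrame(
            {"m": [np.nan, np.nan, np.nan, 1.0, 2.0, 3.0, 4.0, 5.0]},
            index=list(toy_design.group_of),
        )
        with caplog.at_level(logging.WARNING, logger="devindex"):
            pdi = pdi_table(OmicsMatrix(df, "physiology"), toy_design)
        assert pdi["m"].isna().all()
        assert any("no baseline values" in r.message for r in caplog.records)
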