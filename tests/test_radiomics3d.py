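"""The 269-feature 3D battery against brute-force oracles and analytic
limits."""

import numpy as np
import pytest

from myotex import radiomics3d as r3
from myotex.radiomics3d import (DiscretizationConfig, extract_all,
                                feature_manifest, first_order_features,
                                glcm3d_features, gldzm_features,
                                glrlm_features, glszm_features,
                                morphology_features, ngldm_features,
                                ngtdm_features)
import _oracles as orc

DISC4 = DiscretizationConfig(n_levels=4)


@pytest.fixture(scope="module")
def toy(toy_volume_mask):
    vol, mask = toy_volume_mask
    lev = orc.quantize_fbn(vol, mask, 4)
    return vol, mask, lev


class TestCounts:
    def test_family_counts(self, toy):
        vol, mask, _ = toy
        assert len(first_order_features(vol, mask, DISC4)) == 50
        assert len(morphology_features(mask)) == 29
        assert len(glcm3d_features(vol, mask, DISC4)) == 50
        assert len(glrlm_features(vol, mask, DISC4)) == 32
        assert len(glszm_features(vol, mask, DISC4)) == 32
        assert len(gldzm_features(vol, mask, DISC4)) == 32
        assert len(ngtdm_features(vol, mask, DISC4)) == 10
        assert len(ngldm_features(vol, mask, DISC4)) == 34

    def test_battery_is_269_unique_and_compositional(self, toy):
        vol, mask, _ = toy
        feats = extract_all(vol, mask, DISC4)
        assert len(feats) == 269
        assert len(set(feats)) == 269
        repeat = extract_all(vol, mask, DISC4)
        assert feats == repeat
        parts = {}
        for fn in (first_order_features, glcm3d_features, glrlm_features,
                   glszm_features, gldzm_features, ngtdm_features,
                   ngldm_features):
            parts.update(fn(vol, mask, DISC4))
        parts.update(morphology_features(mask, (1, 1, 1), volume=vol))
        assert feats == parts

    def test_manifest_matches_battery(self, toy):
        vol, mask, _ = toy
        manifest = feature_manifest()
        assert len(manifest) == 269
        assert [m["name"] for m in manifest] == list(extract_all(vol, mask, DISC4))


class TestGLCM3D:
    def test_merged_matches_pair_enumeration_oracle(self, toy):
        vol, mask, lev = toy
        merged = sum(orc.glcm_matrix_3d(lev, mask, off, 4)
                     for off in orc.OFFSETS_3D)
        expected = orc.glcm25_oracle(merged)
        got = glcm3d_features(vol, mask, DISC4)
        for name, v in expected.items():
            assert got[f"GLCM_{name}"] == pytest.approx(v, abs=1e-9), name

    def test_averaged_matches_per_direction_oracle(self, toy):
        vol, mask, lev = toy
        per_dir = [orc.glcm25_oracle(orc.glcm_matrix_3d(lev, mask, off, 4))
                   for off in orc.OFFSETS_3D]
        got = glcm3d_features(vol, mask, DISC4)
        for name in ("Contrast", "ClusterTendency", "JointEntropy", "IMC2",
                     "Correlation", "Autocorrelation"):
            expected = np.mean([d[name] for d in per_dir])
            assert got[f"GLCM_{name}_Avg"] == pytest.approx(expected, abs=1e-9)

    def test_constant_roi_degenerate(self):
        vol = np.ones((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        got = glcm3d_features(vol, mask, DISC4)
        assert got["GLCM_Contrast"] == 0.0
        assert got["GLCM_ClusterTendency"] == 0.0
        assert got["GLCM_Contrast_Avg"] == 0.0
        assert got["GLCM_ClusterTendency_Avg"] == 0.0

    def test_single_voxel_rejected(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError):
            glcm3d_features(np.ones((3, 3, 3)), mask, DISC4)


class TestGLRLM:
    def test_matches_run_scanning_oracle(self, toy):
        vol, mask, lev = toy
        mats = [orc.run_matrix_oracle(lev, mask, off, 4)
                for off in orc.OFFSETS_3D]
        width = max(m.shape[1] for m in mats)
        mats_p = [np.pad(m, ((0, 0), (0, width - m.shape[1]))) for m in mats]
        merged = np.sum(mats_p, axis=0)
        nvox = float(mask.sum())
        expected = orc.matrix_stats_oracle(
            merged, list(range(1, width + 1)), nvox * 13, r3.GLRLM_NAMES)
        got = glrlm_features(vol, mask, DISC4)
        for name, v in expected.items():
            assert got[name] == pytest.approx(v, abs=1e-9), name
        per_dir = [orc.matrix_stats_oracle(m, list(range(1, m.shape[1] + 1)),
                                           nvox, r3.GLRLM_NAMES) for m in mats]
        for name in r3.GLRLM_NAMES:
            exp = np.mean([d[name] for d in per_dir])
            assert got[f"{name}_Avg"] == pytest.approx(exp, abs=1e-9), name

    def test_single_voxel_runs(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        got = glrlm_features(np.ones((3, 3, 3)), mask, DISC4)
        assert got["GLRLM_SRE"] == 1.0 and got["GLRLM_LRE"] == 1.0


class TestGLSZM:
    def test_matches_component_oracle(self, toy):
        vol, mask, lev = toy
        M = orc.szm_oracle(lev, mask, 4)
        expected = orc.matrix_stats_oracle(
            M, list(range(1, M.shape[1] + 1)), float(mask.sum()),
            r3.GLSZM_NAMES)
        got = glszm_features(vol, mask, DISC4)
        for name, v in expected.items():
            assert got[name] == pytest.approx(v, abs=1e-9), name

    def test_slice_aggregation_matches_oracle(self, toy):
        vol, mask, lev = toy
        rows = []
        for z in range(lev.shape[2]):
            if mask[:, :, z].any():
                M = orc.szm_oracle(lev[:, :, z], mask[:, :, z], 4)
                rows.append(orc.matrix_stats_oracle(
                    M, list(range(1, M.shape[1] + 1)),
                    float(mask[:, :, z].sum()), r3.GLSZM_NAMES))
        got = glszm_features(vol, mask, DISC4)
        for name in r3.GLSZM_NAMES:
            exp = np.mean([r[name] for r in rows])
            assert got[f"{name}_2D"] == pytest.approx(exp, abs=1e-9), name

    def test_constant_roi_single_zone(self):
        vol = np.ones((3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        got = glszm_features(vol, mask, DISC4)
        assert got["GLSZM_ZSNU"] == 1.0  # one zone
        assert got["GLSZM_GLNU"] == 1.0


class TestGLDZM:
    def test_matches_distance_oracle(self, toy):
        vol, mask, lev = toy
        M = orc.dzm_oracle(lev, mask, 4)
        expected = orc.matrix_stats_oracle(
            M, list(range(1, M.shape[1] + 1)), float(mask.sum()),
            r3.GLDZM_NAMES)
        got = gldzm_features(vol, mask, DISC4)
        for name, v in expected.items():
            assert got[name] == pytest.approx(v, abs=1e-9), name

    def test_single_voxel_zone_distance_one(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        got = gldzm_features(np.ones((3, 3, 3)), mask, DISC4)
        assert got["GLDZM_SDE"] == 1.0  # one zone at distance 1


class TestNGTDM:
    def test_matches_neighbourhood_oracle(self, toy):
        vol, mask, lev = toy
        expected = orc.ngtdm_stats_oracle(*orc.ngtdm_oracle(lev, mask, 4))
        got = ngtdm_features(vol, mask, DISC4)
        for name, v in expected.items():
            assert got[name] == pytest.approx(v, abs=1e-9), name

    def test_slice_complexity_matches_oracle(self):
        rng = np.random.default_rng(0)
        vol = rng.integers(0, 10, (4, 4, 1)).astype(float)
        mask = np.ones((4, 4, 1), bool)
        lev = orc.quantize_fbn(vol, mask, 4)
        expected = orc.ngtdm_stats_oracle(
            *orc.ngtdm_oracle(lev[:, :, 0], mask[:, :, 0], 4))
        got = ngtdm_features(vol, mask, DISC4)
        assert got["NGTDM_Complexity_2D"] == pytest.approx(
            expected["NGTDM_Complexity"], abs=1e-9)

    def test_constant_roi(self):
        got = ngtdm_features(np.ones((3, 3, 3)), np.ones((3, 3, 3), bool),
                             DISC4)
        assert got["NGTDM_Complexity"] == 0.0
        assert got["NGTDM_Contrast"] == 0.0
        assert got["NGTDM_Coarseness"] == pytest.approx(1e12)  # epsilon guard


class TestNGLDM:
    def test_matches_neighbour_counting_oracle(self, toy):
        vol, mask, lev = toy
        M = orc.ngldm_oracle(lev, mask, 4)
        expected = orc.matrix_stats_oracle(
            M, list(range(1, M.shape[1] + 1)), float(mask.sum()),
            [n for n in r3.NGLDM_BASE if n != "NGLDM_DCEnergy"])
        got = ngldm_features(vol, mask, DISC4)
        for name, v in expected.items():
            assert got[name] == pytest.approx(v, abs=1e-9), name

    def test_single_voxel_low_dependence(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        got = ngldm_features(np.ones((3, 3, 3)), mask, DISC4)
        assert got["NGLDM_LDE"] == 1.0  # dependence count 0 -> column 1


class TestFirstOrder:
    def test_constant_roi_degenerate(self):
        got = first_order_features(np.full((3, 3, 3), 4.0),
                                   np.ones((3, 3, 3), bool), DISC4)
        assert got["FO_Variance"] == 0.0
        assert got["FO_Entropy_IntHist"] == 0.0
        assert got["FO_Uniformity_IntHist"] == 1.0

    def test_moment_oracle(self, toy):
        vol, mask, _ = toy
        got = first_order_features(vol, mask, DISC4)
        x = vol[mask]
        assert got["FO_Mean"] == pytest.approx(x.mean(), abs=1e-9)
        assert got["FO_Variance"] == pytest.approx(x.var(), abs=1e-9)
        mean, sd = x.mean(), x.std()
        assert got["FO_Skewness"] == pytest.approx(
            ((x - mean) ** 3).mean() / sd ** 3, abs=1e-9)
        assert got["FO_Kurtosis"] == pytest.approx(
            ((x - mean) ** 4).mean() / sd ** 4, abs=1e-9)
        assert got["FO_Energy"] == pytest.approx((x ** 2).sum(), abs=1e-9)
        # histogram statistics on the discretized levels
        lev = orc.quantize_fbn(vol, mask, 4)[mask]
        p = np.bincount(lev, minlength=5)[1:] / len(lev)
        assert got["FO_Uniformity_IntHist"] == pytest.approx((p ** 2).sum(),
                                                             abs=1e-9)
        assert got["FO_Entropy_IntHist"] == pytest.approx(
            -sum(q * np.log2(q) for q in p if q > 0), abs=1e-9)


@pytest.fixture(scope="module")
def sphere():
    r = 10
    g = np.ogrid[-12:13, -12:13, -12:13]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r ** 2


class TestMorphology:

    def test_sphere_volume_within_2pct(self, sphere):
        got = morphology_features(sphere, (1.0, 1.0, 1.0))
        analytic = 4.0 / 3.0 * np.pi * 10 ** 3
        assert got["Morph_VolumeMesh"] == pytest.approx(analytic, rel=0.02)

    def test_sphere_sphericity_within_2pct(self, sphere):
        got = morphology_features(sphere, (1.0, 1.0, 1.0))
        assert got["Morph_Sphericity"] == pytest.approx(1.0, rel=0.02)
        assert got["Morph_Max3DDiameter"] == pytest.approx(21.0, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            morphology_features(np.zeros((3, 3, 3), bool))


class TestInvariances:
    def test_constant_shift_invariance_under_fbn(self, toy):
        vol, mask, _ = toy
        a = extract_all(vol, mask, DISC4)
        b = extract_all(vol + 37.0, mask, DISC4)
        for name in a:
            if name.startswith(("GLCM", "GLRLM", "GLSZM", "GLDZM", "NGTDM",
                                "NGLDM")) or name.endswith("_IntHist"):
                assert a[name] == pytest.approx(b[name], abs=1e-9), name

    def test_merged_equals_averaged_on_constant(self):
        vol = np.ones((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        got = glcm3d_features(vol, mask, DISC4)
        for name in r3.GLCM_FEATURES:
            assert got[f"GLCM_{name}"] == pytest.approx(
                got[f"GLCM_{name}_Avg"], abs=1e-12)
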