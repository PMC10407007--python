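"""The in-house 2D extractor: GLCM/Haralick, sliding kernels, aggregation
statistics, LAWS and Gabor banks."""

import numpy as np
import pytest

from myotex.phantom import make_texture_fixture
from myotex.texture2d import (AGG_STATS, GLCMConfig, GaborBankConfig,
                              HARALICK_NAMES, CooccurrenceMatrix, aggregate,
                              extract_slice_features, gabor_features,
                              gabor_kernels, glcm, haralick14, haralick_maps,
                              laws_features, laws_kernels,
                              median_image_features, perpixel_map)
from _oracles import glcm_matrix_2d, haralick_oracle, quantize_fbn


class TestGLCM:
    def test_vertical_pairs_hand_count(self):
        img = np.array([[1, 2], [1, 2]])
        m = glcm(img, GLCMConfig(orientations=(90.0,), n_levels=2),
                 levels="given")
        np.testing.assert_allclose(m.probs, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_window_single_diagonal_entry(self):
        m = glcm(np.ones((5, 5)), GLCMConfig(n_levels=4))
        assert m.probs[0, 0] == 1.0 and m.probs.sum() == 1.0

    def test_probability_mass_conserved(self):
        rng = np.random.default_rng(0)
        for L in (4, 8, 16):
            m = glcm(rng.random((9, 9)), GLCMConfig(n_levels=L))
            assert abs(m.probs.sum() - 1.0) < 1e-9

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.random((7, 7))
        cfg = GLCMConfig(orientations=(0.0, 45.0, 90.0, 135.0), n_levels=4)
        lev = quantize_fbn(img, np.ones_like(img, bool), 4)
        expected = sum(glcm_matrix_2d(lev, off) for off in
                       [(0, 1), (1, 1), (1, 0), (1, -1)])
        m = glcm(img, cfg)
        np.testing.assert_allclose(m.probs, expected / expected.sum(),
                                   atol=1e-12)

    def test_window_smaller_than_offset(self):
        with pytest.raises(ValueError):
            glcm(np.ones((2, 2)), GLCMConfig(distance=3))


class TestHaralick:
    def test_returns_exactly_14_named_values(self):
        m = glcm(np.random.default_rng(0).random((8, 8)),
                 GLCMConfig(n_levels=8))
        feats = haralick14(m)
        assert tuple(feats) == HARALICK_NAMES and len(feats) == 14

    def test_constant_window_degenerates(self):
        feats = haralick14(glcm(np.ones((5, 5)), GLCMConfig(n_levels=4)))
        assert feats["Energy"] == 1.0
        assert feats["Entropy"] == 0.0
        assert feats["Contrast"] == 0.0

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(7)
        raw = rng.random((3, 3)) + rng.random((3, 3)).T  # symmetric-ish
        P = (raw + raw.T)
        P /= P.sum()
        mine = haralick14(CooccurrenceMatrix(P, GLCMConfig(n_levels=3)))
        expected = haralick_oracle(P)
        for name in HARALICK_NAMES:
            assert mine[name] == pytest.approx(expected[name], abs=1e-10), name

    def test_intensity_rescale_invariance(self):
        rng = np.random.default_rng(3)
        img = rng.random((12, 12))
        cfg = GLCMConfig(n_levels=8)
        f1 = haralick14(glcm(img, cfg))
        f2 = haralick14(glcm(5.0 * img + 3.0, cfg))
        for name in HARALICK_NAMES:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12)


class TestPerPixel:
    def test_constant_image_constant_map(self):
        fmap = perpixel_map(np.full((9, 9), 2.0), None, np.mean, 3)
        assert np.all(fmap.values[fmap.support] == 2.0)

    def test_spot_check_against_direct_patch(self):
        rng = np.random.default_rng(4)
        img = rng.random((11, 11))
        fmap = perpixel_map(img, None, np.std, 5)
        r, c = 6, 4
        assert fmap.values[r, c] == pytest.approx(
            np.std(img[r - 2:r + 3, c - 2:c + 3]))

    def test_support_excludes_border(self):
        fmap = perpixel_map(np.ones((9, 9)), None, np.mean, 7)
        assert not fmap.support[:3].any() and not fmap.support[:, :3].any()
        assert fmap.support[3:-3, 3:-3].all()

    def test_fast_haralick_maps_match_slow_path(self):
        """The integral-image per-pixel Haralick equals the generic sliding
        window + glcm + haralick14 route."""
        rng = np.random.default_rng(5)
        img = rng.random((12, 12))
        cfg = GLCMConfig(n_levels=4)
        fast = haralick_maps(img, None, cfg, kernel_size=5)
        from myotex.preprocess import quantize

        lev = quantize(img, None, 4).levels

        def slow_fn(name):
            def fn(patch):
                return haralick14(glcm(patch, cfg, levels="given"))[name]
            return fn

        for name in ("Energy", "Contrast", "Entropy", "DiffAvg", "IMC2"):
            slow = perpixel_map(lev, None, slow_fn(name), 5)
            np.testing.assert_allclose(
                fast[name].values[fast[name].support],
                slow.values[slow.support], atol=1e-10, err_msg=name)


class TestAggregate:
    def test_symmetric_sample(self):
        s = aggregate(np.array([[1, 2, 3, 4, 5]], float))
        assert s.average == 3 and s.median == 3 and s.skewness == 0

    def test_moment_oracle(self):
        v = np.array([1.0, 1.0, 1.0, 10.0])
        s = aggregate(v.reshape(2, 2))
        mean = v.mean()
        var = ((v - mean) ** 2).mean()
        assert s.variance == pytest.approx(var)
        assert s.skewness == pytest.approx(((v - mean) ** 3).mean() / var ** 1.5)
        assert s.kurtosis == pytest.approx(((v - mean) ** 4).mean() / var ** 2)

    def test_constant_conventions(self):
        with pytest.warns(UserWarning):
            s = aggregate(np.full((3, 3), 5.0))
        assert (s.variance, s.skewness, s.kurtosis) == (0.0, 0.0, 0.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            aggregate(np.ones((1, 1)))


class TestLaws:
    def test_25_kernels_and_zero_sums(self):
        kers = laws_kernels()
        assert len(kers) == 25
        for name, k in kers.items():
            if name == "L5L5":
                assert k.sum() == 256
            else:
                assert abs(k.sum()) < 1e-12

    def test_constant_image_zero_energy(self):
        _, feats = laws_features(np.full((16, 16), 3.0))
        for name, v in feats.items():
            if "L5L5" not in name and "Average" in name:
                assert abs(v) < 1e-9, name

    def test_feature_count(self):
        _, feats = laws_features(np.random.default_rng(0).random((16, 16)))
        assert len(feats) == 125  # 25 masks x 5 statistics


class TestGabor:
    def test_default_bank_has_48_filters(self):
        assert GaborBankConfig().n_filters() == 48
        assert len(gabor_kernels(GaborBankConfig())) == 48

    def test_grating_peaks_at_matching_filter(self):
        img = make_texture_fixture("grating", (64, 64), wavelength=8,
                                   orientation_deg=45)
        feats = gabor_features(img.pixels)
        avg = {k: v for k, v in feats.items() if k.startswith("Gabor_Average")}
        best = max(avg, key=avg.get)
        assert best == "Gabor_Average_W8O45"

    def test_constant_image_zero_response(self):
        feats = gabor_features(np.full((32, 32), 5.0))
        for k, v in feats.items():
            if "Average" in k:
                assert abs(v) < 1e-8, k

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            gabor_features(np.ones((16, 16)),
                           bank=GaborBankConfig(wavelengths=(1.5,)))


class TestMedianImage:
    def test_constant(self):
        feats = median_image_features(np.full((8, 8), 2.0))
        assert feats["FO_Variance_ImgMed"] == 0.0

    def test_spike_removed(self):
        img = np.full((9, 9), 1.0)
        img[4, 4] = 100.0
        feats = median_image_features(img)
        assert feats["FO_Variance_ImgMed"] < img.var()
        assert feats["FO_Variance_ImgMed"] == 0.0  # median removes the spike

    def test_paper_name_present(self):
        feats = median_image_features(np.random.default_rng(0).random((8, 8)))
        assert "FO_Variance_ImgMed" in feats


def test_full_slice_battery_size_and_determinism():
    rng = np.random.default_rng(9)
    img = rng.random((32, 32))
    f1 = extract_slice_features(img)
    f2 = extract_slice_features(img)
    assert len(f1) == 14 * 5 + 25 * 5 + 48 * 5 + 5 == 440
    assert f1 == f2
    assert "Gabor_Median_W5O135" in f1 and "Haralick_Kurtosis_DiffAvg" in f1 \
        and "LAWS_Skewness_R5E5" in f1
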