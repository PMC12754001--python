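import numpy as np
import pytest

from ctiqa import phantoms
from ctiqa._errors import ValidationError
from ctiqa.features import (
    FEATURE_NAMES,
    compute_glcm,
    diagnostic_features,
    distribution_features,
    edge_features,
    edge_map,
    extract_all,
    features_to_table,
    frequency_features,
    glcm_features,
    intensity_features,
    lbp_codes,
    lbp_features,
    read_table,
    write_table,
)
from ctiqa.io_prep import GrayImage

from ._oracles import glcm_reference, lbp_reference
from .conftest import random_gray


def gray(arr):
    return GrayImage(pixels_float=np.asarray(arr, dtype=np.float64))


class TestIntensity:
    def test_constant_image_degenerates(self, constant_image):
        f = intensity_features(constant_image)
        assert f["int_min"] == f["int_max"] == f["int_mean"] == 0.5
        assert f["int_median"] == f["int_p10"] == f["int_p90"] == 0.5
        assert f["int_std"] == f["int_range"] == 0.0
        assert f["int_skewness"] == f["int_kurtosis"] == 0.0

    def test_half_zero_half_one(self):
        px = np.zeros((8, 8))
        px[4:, :] = 1.0
        f = intensity_features(gray(px))
        assert f["int_mean"] == pytest.approx(0.5)
        assert f["int_std"] == pytest.approx(0.5)
        assert f["int_range"] == 1.0
        assert f["int_skewness"] == pytest.approx(0.0)

    def test_bounds_inherited_from_gray_image(self, rng):
        f = intensity_features(random_gray(rng, 16))
        assert 0.0 <= f["int_min"] <= f["int_max"] <= 1.0


class TestDistribution:
    def test_constant_single_bin(self, constant_image):
        f = distribution_features(constant_image)
        assert f["hist_entropy"] == 0.0
        assert f["hist_energy"] == 1.0
        assert f["hist_mode"] == float(constant_image.pixels_u8[0, 0])

    def test_two_equal_intensities(self):
        px = np.zeros((8, 8))
        px[:, 4:] = 1.0
        f = distribution_features(gray(px))
        assert f["hist_entropy"] == pytest.approx(1.0)
        assert f["hist_energy"] == pytest.approx(0.5)
        assert f["hist_mode"] == 0.0  # tie resolves to smaller intensity

    def test_uniform_256_bins(self):
        px = (np.arange(256, dtype=np.float64) / 255.0).reshape(16, 16)
        f = distribution_features(gray(px))
        assert f["hist_entropy"] == pytest.approx(8.0)
        assert f["hist_energy"] == pytest.approx(1.0 / 256.0)

    def test_entropy_within_bit_bounds(self, rng):
        f = distribution_features(random_gray(rng, 32))
        assert 0.0 <= f["hist_entropy"] <= 8.0


class TestEdges:
    def test_constant_image_empty_map(self, constant_image):
        assert not edge_map(constant_image).any()
        f = edge_features(constant_image)
        assert f["edge_count"] == 0.0
        assert f["region_area"] == 0.0
        assert f["region_circularity"] == 0.0

    def test_vertical_step_localized_edges(self):
        px = np.zeros((32, 32))
        px[:, 16:] = 1.0
        em = edge_map(gray(px))
        assert em.any()
        cols = np.where(em)[1]
        assert np.all(np.abs(cols - 15.5) <= 1.5)

    def test_edge_map_is_binary(self, rng):
        em = edge_map(random_gray(rng, 32))
        assert em.dtype == bool

    def test_disc_circularity_near_one(self):
        from skimage.draw import disk

        px = np.full((224, 224), 0.05)
        rr, cc = disk((112, 112), 50)
        px[rr, cc] = 0.9
        f = edge_features(gray(px))
        assert 0.85 <= f["region_circularity"] <= 1.05

    def test_disc_rounder_than_square(self):
        # equal-area shapes: the disc wins on the isoperimetric ratio
        from skimage.draw import disk

        pd = np.full((128, 128), 0.05)
        rr, cc = disk((64, 64), 30)
        pd[rr, cc] = 0.9
        side = int(round(np.sqrt(np.pi) * 30))
        ps = np.full((128, 128), 0.05)
        ps[30:30 + side, 30:30 + side] = 0.9
        circ_d = edge_features(gray(pd))["region_circularity"]
        circ_s = edge_features(gray(ps))["region_circularity"]
        assert circ_d > circ_s


class TestDiagnostic:
    def test_constant_image_all_zero(self, constant_image):
        f = diagnostic_features(constant_image)
        assert all(v == 0.0 for v in f.values())

    def test_noise_monotonicity_over_seeds(self):
        """Rising additive noise lowers SNR and raises heterogeneity."""
        base = phantoms.make_clean_phantom(seed=7, side=96).pixels_float
        sigmas = [0.02, 0.05, 0.10]
        snr_means, het_means = [], []
        for sigma in sigmas:
            snrs, hets = [], []
            for s in range(20):
                r = np.random.default_rng(1000 + s)
                noisy = np.clip(base + r.normal(0, sigma, base.shape), 0, 1)
                f = diagnostic_features(gray(noisy))
                snrs.append(f["snr"])
                hets.append(f["texture_heterogeneity"])
            snr_means.append(np.mean(snrs))
            het_means.append(np.mean(hets))
        assert snr_means[0] > snr_means[1] > snr_means[2]
        assert het_means[0] < het_means[1] < het_means[2]


class TestFrequency:
    def test_constant_image_dc_only(self, constant_image):
        f = frequency_features(constant_image)
        assert f["freq_sum"] == 0.0
        assert f["freq_max"] == 0.0
        assert f["spectral_flatness"] == pytest.approx(1.0)

    def test_white_noise_flatter_than_phantom(self):
        flat_noise, flat_smooth = [], []
        for s in range(20):
            r = np.random.default_rng(s)
            flat_noise.append(
                frequency_features(gray(r.random((96, 96))))["spectral_flatness"]
            )
            smooth = phantoms.make_clean_phantom(seed=s, side=96)
            flat_smooth.append(frequency_features(smooth)["spectral_flatness"])
        # a white spectrum has exponentially distributed power, whose
        # geometric/arithmetic mean ratio is e^(−γ) ≈ 0.561
        assert np.mean(flat_noise) > np.mean(flat_smooth)
        assert np.mean(flat_noise) == pytest.approx(np.exp(-0.5772), rel=0.05)

    def test_high_freq_sum_is_subset_sum(self, rng):
        for _ in range(5):
            f = frequency_features(random_gray(rng, 24))
            assert f["high_freq_sum"] <= f["freq_sum"]


class TestGLCM:
    def test_two_value_rows_pair_probabilities(self):
        px = np.zeros((8, 8))
        px[4:, :] = 1.0
        g = compute_glcm(gray(px), levels=8)
        # horizontal pairs only pair equal values → two cells at 0.5
        assert g.probabilities[0, 0] == pytest.approx(0.5)
        assert g.probabilities[7, 7] == pytest.approx(0.5)
        assert g.probabilities.sum() == pytest.approx(1.0)

    def test_constant_single_cell(self, constant_image):
        g = compute_glcm(constant_image)
        assert g.probabilities.max() == pytest.approx(1.0)
        assert (g.probabilities > 0).sum() == 1

    def test_matches_double_loop_reference(self, rng):
        for _ in range(10):
            img = random_gray(rng, 16)
            g = compute_glcm(img)
            np.testing.assert_array_equal(
                g.probabilities, glcm_reference(img.pixels_u8)
            )

    def test_distance_beyond_side_rejected(self, constant_image):
        with pytest.raises(ValidationError):
            compute_glcm(constant_image, d=32)


class TestGLCMFeatures:
    def test_constant_image_degenerates(self, constant_image):
        f = glcm_features(compute_glcm(constant_image))
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_dissimilarity"] == 0.0
        assert f["glcm_homogeneity"] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_max_probability"] == pytest.approx(1.0)
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_correlation"] == 1.0

    def test_checkerboard_contrast(self):
        px = np.indices((16, 16)).sum(axis=0) % 2
        f = glcm_features(compute_glcm(gray(px.astype(float))))
        # every horizontal pair jumps between levels 0 and 255
        assert f["glcm_contrast"] == pytest.approx(255.0**2)

    def test_energy_below_max_probability(self, rng):
        for _ in range(5):
            f = glcm_features(compute_glcm(random_gray(rng, 16)))
            assert f["glcm_energy"] <= f["glcm_max_probability"] <= 1.0
            assert f["glcm_entropy"] >= 0.0


class TestLBP:
    def test_constant_image_codes_all_255(self, constant_image):
        codes = lbp_codes(constant_image.pixels_u8)
        assert np.all(codes == 255)
        f = lbp_features(constant_image)
        assert f["lbp_mean"] == 255.0
        assert f["lbp_variance"] == 0.0

    def test_bright_center_codes_zero(self):
        px = np.zeros((9, 9))
        px[4, 4] = 1.0
        codes = lbp_codes(gray(px).pixels_u8)
        assert codes[3, 3] == 0  # the bright pixel's own code

    def test_matches_double_loop_reference(self, rng):
        for _ in range(10):
            img = random_gray(rng, 16)
            np.testing.assert_array_equal(
                lbp_codes(img.pixels_u8), lbp_reference(img.pixels_u8)
            )

    def test_mean_within_code_range(self, rng):
        f = lbp_features(random_gray(rng, 16))
        assert 0.0 <= f["lbp_mean"] <= 255.0

    def test_too_small_image_rejected(self):
        with pytest.raises(ValidationError):
            lbp_codes(np.zeros((3, 3), dtype=np.uint8))


class TestExtractAll:
    def test_canonical_order_and_finiteness(self, rng):
        vec = extract_all(random_gray(rng, 32))
        assert tuple(vec) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in vec.values())

    def test_deterministic(self, rng):
        img = random_gray(rng, 32)
        v1, v2 = extract_all(img), extract_all(img)
        assert v1 == v2

    def test_constant_image_full_vector(self, constant_image):
        vec = extract_all(constant_image)
        assert vec["int_std"] == 0.0
        assert vec["edge_count"] == 0.0
        assert vec["snr"] == 0.0
        assert vec["glcm_correlation"] == 1.0
        assert vec["lbp_variance"] == 0.0


class TestFeatureTable:
    def test_round_trip(self, rng, tmp_path):
        vecs = [extract_all(random_gray(rng, 16)) for _ in range(3)]
        df = features_to_table(vecs, [0.5, 2.0, 3.5])
        assert df.shape == (3, 40)
        p = tmp_path / "t.csv"
        write_table(df, p)
        back = read_table(p)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), rtol=1e-11)

    def test_empty_table_header_only(self):
        df = features_to_table([])
        assert df.shape == (0, 39)
        assert list(df.columns) == list(FEATURE_NAMES)

    def test_length_mismatch_rejected(self, rng):
        vecs = [extract_all(random_gray(rng, 16))]
        with pytest.raises(ValidationError):
            features_to_table(vecs, [1.0, 2.0])
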