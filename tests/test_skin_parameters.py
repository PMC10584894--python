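import itertools
import math

import numpy as np
import pytest

import hfus
from hfus.skin_parameters import (
    GLCMConfig,
    IntensityBand,
    glcm,
    glcm_features,
    lep_upper_lower_ratio,
    pixel_fraction,
    quantize,
    region_entropy,
    surface_roughness,
    thickness,
)

PARTITION_BANDS = [IntensityBand(0, 30), IntensityBand(31, 49), IntensityBand(50, 150),
                   IntensityBand(151, 199), IntensityBand(200, 255)]


def _image(arr):
    return hfus.BModeImage(np.asarray(arr, dtype=np.uint8))


def _boundary_from_rows(top_rows, n_rows=None, thickness_px=1):
    top = np.asarray(top_rows)
    m = np.zeros(((n_rows or top.max() + thickness_px + 1), len(top)), dtype=bool)
    for c, t in enumerate(top):
        m[t : t + thickness_px, c] = True
    return hfus.extract_boundaries(hfus.LayerMask(m, "external"))


# ---------------------------------------------------------------------------
# thickness / echogenicity / fractions
# ---------------------------------------------------------------------------

class TestThickness:
    def test_flat_band(self):
        b = _boundary_from_rows([100] * 50, n_rows=200, thickness_px=41)
        assert thickness(b, hfus.PixelCalibration()) == pytest.approx(41 * 0.0023)

    def test_single_pixel_layer(self):
        b = _boundary_from_rows([5, 5, 5], thickness_px=1)
        assert thickness(b, hfus.PixelCalibration()) == pytest.approx(0.0023)

    def test_phantom_recovery_within_5pct(self, segmented_phantom):
        spec, image, truth, mask = segmented_phantom
        b = hfus.extract_boundaries(mask)
        t = thickness(b, image.calibration)
        assert t == pytest.approx(truth.thickness_mm, rel=0.05)


class TestEchogenicity:
    def test_uniform_region(self):
        img = _image(np.full((10, 10), 37))
        assert hfus.echogenicity(img, np.ones((10, 10), bool)) == 37.0

    def test_bimodal_region(self):
        arr = np.zeros((2, 2), dtype=np.uint8)
        arr[0] = 255
        assert hfus.echogenicity(_image(arr), np.ones((2, 2), bool)) == 127.5

    def test_empty_region_rejected(self):
        with pytest.raises(hfus.MeasurementError):
            hfus.echogenicity(_image(np.zeros((4, 4))), np.zeros((4, 4), bool))


class TestIntensityRatio:
    def test_quarter(self):
        assert hfus.intensity_ratio(50.0, 200.0) == 0.25

    def test_identity(self):
        assert hfus.intensity_ratio(123.0, 123.0) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(hfus.MeasurementError):
            hfus.intensity_ratio(10.0, 0.0)


class TestPixelFraction:
    def test_ten_listed_values_brute_force(self):
        vals = [0, 10, 30, 31, 49, 50, 150, 151, 199, 200]
        img = _image(np.array([vals]))
        roi = np.ones((1, 10), bool)
        assert pixel_fraction(img, roi, hfus.DEFAULT_BANDS["LEP"]) == 30.0
        assert pixel_fraction(img, roi, hfus.DEFAULT_BANDS["MEP"]) == 20.0
        assert pixel_fraction(img, roi, hfus.DEFAULT_BANDS["HEP"]) == 10.0

    def test_uniform_dark_region_is_all_lep(self):
        img = _image(np.zeros((5, 5)))
        assert pixel_fraction(img, np.ones((5, 5), bool), hfus.DEFAULT_BANDS["LEP"]) == 100.0

    def test_uniform_mid_region(self):
        img = _image(np.full((5, 5), 100))
        roi = np.ones((5, 5), bool)
        assert pixel_fraction(img, roi, hfus.DEFAULT_BANDS["MEP"]) == 100.0
        assert pixel_fraction(img, roi, hfus.DEFAULT_BANDS["LEP"]) == 0.0
        assert pixel_fraction(img, roi, hfus.DEFAULT_BANDS["HEP"]) == 0.0

    def test_partition_sums_to_100_on_random_regions(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            arr = rng.integers(0, 256, size=(30, 30))
            img = _image(arr)
            roi = rng.random((30, 30)) < 0.5
            if not roi.any():
                continue
            fractions = [pixel_fraction(img, roi, b) for b in PARTITION_BANDS]
            counts = [round(f * roi.sum() / 100) for f in fractions]
            assert sum(counts) == roi.sum()
            assert sum(fractions) == pytest.approx(100.0, abs=1e-9)


class TestLepRatio:
    @pytest.mark.parametrize("up,lo,expected", [(20.0, 10.0, 2.0), (7.5, 7.5, 1.0)])
    def test_ratio(self, up, lo, expected):
        assert lep_upper_lower_ratio(up, lo) == expected

    def test_zero_denominator_is_missing(self):
        assert math.isnan(lep_upper_lower_ratio(20.0, 0.0))


# ---------------------------------------------------------------------------
# roughness
# ---------------------------------------------------------------------------

class TestSurfaceRoughness:
    def test_flat_boundary_exactly_one(self):
        b = _boundary_from_rows([50] * 30)
        assert surface_roughness(b, hfus.PixelCalibration()) == 1.0

    def test_unit_zigzag_is_sqrt2(self):
        b = _boundary_from_rows([0, 1, 0], n_rows=5)
        cal = hfus.PixelCalibration(1.0, 1.0)
        assert surface_roughness(b, cal) == pytest.approx(math.sqrt(2.0))

    def test_gaps_split_polyline(self):
        top = np.array([5, 5, 5, 0, 5, 5])
        m = np.zeros((10, 6), dtype=bool)
        for c, t in enumerate(top):
            m[t, c] = True
        m[:, 3] = False  # gap at column 3
        b = hfus.extract_boundaries(hfus.LayerMask(m, "external"))
        cal = hfus.PixelCalibration(1.0, 1.0)
        # segments [0,1,2] and [4,5], all flat: ratio 1
        assert surface_roughness(b, cal) == 1.0

    def test_monotone_in_waviness_amplitude(self):
        ratios = []
        for amp in (0.0, 0.01, 0.02, 0.04):
            wav = ((amp, 0.8),) if amp else ()
            spec = hfus.PhantomSpec(seed=5, boundary_waviness=wav)
            _, truth = hfus.generate_phantom(spec)
            b = hfus.extract_boundaries(hfus.LayerMask(truth.mask, "external"))
            ratios.append(surface_roughness(b, spec.calibration))
        assert all(r2 >= r1 for r1, r2 in zip(ratios, ratios[1:]))
        assert ratios[0] == 1.0

    def test_sinusoidal_boundary_matches_quadrature_within_2pct(self, default_phantom):
        spec, _, truth = default_phantom
        b = hfus.extract_boundaries(hfus.LayerMask(truth.mask, "external"))
        measured = surface_roughness(b, spec.calibration)
        assert measured == pytest.approx(truth.roughness_ratio, rel=0.02)

    def test_too_few_columns_rejected(self):
        b = _boundary_from_rows([5])
        with pytest.raises(hfus.MeasurementError):
            surface_roughness(b, hfus.PixelCalibration())


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def glcm_pair_enumeration_oracle(q, roi, offset, symmetric=True):
    """Exhaustive ordered-pair counting, independent of the array code."""
    levels = int(q.max()) + 1
    n_rows, n_cols = q.shape
    counts = {}
    dr, dc = offset
    for r, c in itertools.product(range(n_rows), range(n_cols)):
        rr, cc = r + dr, c + dc
        if roi[r, c] and 0 <= rr < n_rows and 0 <= cc < n_cols and roi[rr, cc]:
            counts[(q[r, c], q[rr, cc])] = counts.get((q[r, c], q[rr, cc]), 0) + 1
            if symmetric:
                counts[(q[rr, cc], q[r, c])] = counts.get((q[rr, cc], q[r, c]), 0) + 1
    return counts


def _checkerboard_image():
    arr = np.zeros((4, 4), dtype=np.uint8)
    arr[::2, 1::2] = 128  # quantizes to level 1 at levels=2
    arr[1::2, ::2] = 128
    return _image(arr)


class TestGLCM:
    def test_checkerboard_matrix(self):
        img = _checkerboard_image()
        p = glcm(img, np.ones((4, 4), bool), GLCMConfig(offset=(0, 1), levels=2))
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(p, expected)

    def test_constant_region_single_diagonal_entry(self):
        img = _image(np.full((5, 5), 64))
        p = glcm(img, np.ones((5, 5), bool), GLCMConfig(offset=(0, 1), levels=128))
        q = (64 * 128) // 256
        assert p[q, q] == 1.0
        assert p.sum() == 1.0

    def test_normalised_and_nonnegative(self):
        rng = np.random.default_rng(9)
        img = _image(rng.integers(0, 256, size=(12, 12)))
        roi = rng.random((12, 12)) < 0.7
        p = glcm(img, roi, GLCMConfig(offset=(5, 7), levels=16))
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1), (0, 2), (2, 1)])
    def test_matches_pair_enumeration_on_small_regions(self, offset):
        rng = np.random.default_rng(sum(offset) + 17)
        for _ in range(10):
            arr = rng.integers(0, 256, size=(6, 6))
            roi = rng.random((6, 6)) < 0.7
            img = _image(arr)
            cfg = GLCMConfig(offset=offset, levels=8)
            q = quantize(img.intensities, 8)
            oracle = glcm_pair_enumeration_oracle(q, roi, offset)
            total = sum(oracle.values())
            if total == 0:
                with pytest.raises(hfus.MeasurementError):
                    glcm(img, roi, cfg)
                continue
            p = glcm(img, roi, cfg)
            expected = np.zeros((8, 8))
            for (a, b), n in oracle.items():
                expected[a, b] = n / total
            np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_matches_skimage_on_rectangular_region(self):
        skimage_feature = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(21)
        arr = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        img = _image(arr)
        p = glcm(img, np.ones((40, 40), bool), GLCMConfig(offset=(0, 7), levels=256))
        ref = skimage_feature.graycomatrix(arr, distances=[7], angles=[0.0],
                                           levels=256, symmetric=True, normed=True)
        np.testing.assert_allclose(p, ref[:, :, 0, 0], atol=1e-12)

    def test_no_pairs_rejected(self):
        img = _image(np.zeros((3, 3)))
        roi = np.zeros((3, 3), bool)
        roi[0, 0] = True
        with pytest.raises(hfus.MeasurementError):
            glcm(img, roi, GLCMConfig(offset=(0, 1)))


class TestGLCMFeatures:
    def test_checkerboard_closed_form(self):
        img = _checkerboard_image()
        p = glcm(img, np.ones((4, 4), bool), GLCMConfig(offset=(0, 1), levels=2))
        f = glcm_features(p)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)
        assert f["energy"] == pytest.approx(0.5)
        assert f["homogeneity"] == pytest.approx(0.5)

    def test_constant_region_degenerate_features(self):
        img = _image(np.full((5, 5), 64))
        f = glcm_features(glcm(img, np.ones((5, 5), bool), GLCMConfig(offset=(0, 1))))
        assert f["contrast"] == 0.0
        assert f["energy"] == 1.0
        assert f["homogeneity"] == 1.0
        assert math.isnan(f["correlation"])

    def test_feature_bounds_on_random_regions(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            arr = rng.integers(0, 256, size=(15, 15))
            img = _image(arr)
            f = glcm_features(glcm(img, np.ones((15, 15), bool),
                                   GLCMConfig(offset=(1, 1), levels=32)))
            assert 0 < f["energy"] <= 1
            assert 0 < f["homogeneity"] <= 1
            assert -1 <= f["correlation"] <= 1
            assert f["contrast"] >= 0


class TestRegionEntropy:
    def test_constant_region_zero_bits(self):
        img = _image(np.full((6, 6), 42))
        assert region_entropy(img, np.ones((6, 6), bool)) == 0.0

    def test_two_equiprobable_levels_one_bit(self):
        arr = np.zeros((2, 4), dtype=np.uint8)
        arr[1] = 255
        assert region_entropy(_image(arr), np.ones((2, 4), bool)) == pytest.approx(1.0)

    def test_uniform_over_128_levels_is_7_bits(self):
        arr = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert region_entropy(_image(arr), np.ones((16, 16), bool), 128) == pytest.approx(7.0)


class TestIntensityShiftResponse:
    def test_texture_invariant_echogenicity_shifts(self):
        rng = np.random.default_rng(41)
        base = rng.integers(10, 100, size=(20, 20))  # headroom: no clipping
        roi = np.ones((20, 20), bool)
        c = 4  # multiple of the 128-level quantization step (2)
        img0, img1 = _image(base), _image(base + c)
        cfg = GLCMConfig(offset=(0, 3), levels=128)
        f0 = glcm_features(glcm(img0, roi, cfg))
        f1 = glcm_features(glcm(img1, roi, cfg))
        for key in ("contrast", "correlation", "energy", "homogeneity"):
            assert f1[key] == pytest.approx(f0[key], abs=1e-12)
        assert region_entropy(img1, roi) == pytest.approx(region_entropy(img0, roi))
        assert hfus.echogenicity(img1, roi) == hfus.echogenicity(img0, roi) + c


# ---------------------------------------------------------------------------
# full record
# ---------------------------------------------------------------------------

class TestMeasureAll:
    def test_flat_band_composition(self, flat_band_image, flat_band_mask):
        mask = hfus.postprocess_mask(flat_band_mask,
                                     hfus.SegmentationParams(border_px=20))
        rec = hfus.measure_all(flat_band_image, mask)
        assert rec.thickness_mm == pytest.approx(41 * 0.0023)
        assert rec.roughness_edge_ratio == 1.0
        assert rec.echogenicity["entry_echo"] == 220.0
        assert rec.echogenicity["upper_dermis"] == 100.0
        assert rec.intensity_ratio_upper_dermis_to_entry_echo == pytest.approx(100 / 220)
        assert rec.fractions["upper_dermis"]["MEP"] == 100.0
        assert rec.fractions["entry_echo"]["HEP"] == 100.0
        assert math.isnan(rec.nlep_upper_to_lower)  # lower-dermis nLEP is 0
        assert rec.entropy_bits["entry_echo"] == 0.0

    def test_record_invariants(self, segmented_phantom):
        _, image, _, mask = segmented_phantom
        rec = hfus.measure_all(image, mask)
        assert rec.thickness_mm > 0
        assert rec.roughness_edge_ratio >= 1.0
        for roi, f in rec.fractions.items():
            assert 0 <= f["LEP"] + f["MEP"] + f["HEP"] <= 100 + 1e-9
            assert 0 <= rec.echogenicity[roi] <= 255

    def test_deterministic(self, segmented_phantom):
        _, image, _, mask = segmented_phantom
        r1 = hfus.measure_all(image, mask)
        r2 = hfus.measure_all(image, mask)
        assert r1.to_rows() == r2.to_rows()

    def test_empty_mask_rejected(self, flat_band_image):
        empty = hfus.LayerMask(np.zeros(flat_band_image.intensities.shape, bool), "external")
        with pytest.raises(hfus.MeasurementError):
            hfus.measure_all(flat_band_image, empty)
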