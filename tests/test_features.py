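"""Shape measures, color-ratio features, and end-to-end extraction."""

import math

import numpy as np
import pytest
from skimage.draw import disk

from wbckit.colorspaces import CHANNEL_NAMES, feature_channels
from wbckit.cytoplasm import CellRegions
from wbckit.features import (
    FEATURE_NAMES,
    N_FEATURES,
    ExtractionFailedError,
    RegionTooSmallError,
    ShapeMeasure,
    color_features,
    extract_features,
    region_stats,
    shape_features,
    shape_measures,
    traced_perimeter,
)


class TestShapeMeasures:
    def test_filled_square_perimeter_is_36(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        m = shape_measures(CellRegions.from_nucleus(mask))
        assert m.area_nucleus == 100
        assert m.perimeter_nucleus == pytest.approx(36.0)

    def test_tiny_region_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[5:8, 5:8] = True  # 9 px < 16
        with pytest.raises(RegionTooSmallError):
            shape_measures(CellRegions.from_nucleus(mask))

    def test_convex_mask_has_equal_nucleus_and_hull_measures(self):
        mask = np.zeros((30, 30), bool)
        mask[5:20, 8:25] = True
        m = shape_measures(CellRegions.from_nucleus(mask))
        assert m.area_hull == m.area_nucleus
        assert m.perimeter_hull == pytest.approx(m.perimeter_nucleus)


class TestShapeFeatures:
    def test_direct_arithmetic(self):
        m = ShapeMeasure(100, 40, 100, 40)
        sol, conv, circ = shape_features(m)
        assert sol == pytest.approx(1.0)
        assert conv == pytest.approx(1.0)
        assert circ == pytest.approx(1600 / (400 * math.pi))

    def test_analytic_circle_has_unit_circularity(self):
        m = ShapeMeasure(area_nucleus=math.pi * 100, perimeter_nucleus=2 * math.pi * 10,
                         area_hull=math.pi * 100, perimeter_hull=2 * math.pi * 10)
        assert shape_features(m)[2] == pytest.approx(1.0)

    def test_solidity_is_area_ratio(self):
        assert shape_features(ShapeMeasure(50, 30, 100, 28))[0] == pytest.approx(0.5)

    def test_rasterized_disk_near_analytic_values(self):
        # solidity ~1 and convexity ~1 within 3%; circularity carries the
        # +5..9% bias of the traced pixel-center perimeter on smooth curves
        mask = np.zeros((80, 80), bool)
        rr, cc = disk((40, 40), 25.5)
        mask[rr, cc] = True
        sol, conv, circ = shape_features(shape_measures(CellRegions.from_nucleus(mask)))
        assert sol == pytest.approx(1.0, abs=0.03)
        assert conv == pytest.approx(1.0, abs=0.03)
        assert 0.95 <= circ <= 1.12


class TestRegionStats:
    def _regions(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mask[8:12, 13:15] = False  # dent -> non-empty ROC
        return CellRegions.from_nucleus(mask)

    def test_constant_plane(self):
        regions = self._regions()
        st = region_stats(np.full((20, 20), 0.4), regions)
        assert st.mean_nucleus == pytest.approx(0.4)
        assert st.std_nucleus == pytest.approx(0.0)
        assert st.mean_roc == pytest.approx(0.4)

    def test_indicator_plane(self):
        regions = self._regions()
        plane = regions.nucleus.astype(float)
        st = region_stats(plane, regions)
        assert st.mean_nucleus == pytest.approx(1.0)
        assert st.mean_roc == pytest.approx(0.0)

    def test_matches_per_pixel_oracle(self, rng):
        regions = self._regions()
        plane = rng.random((20, 20))
        st = region_stats(plane, regions)
        acc = [plane[i, j] for i in range(20) for j in range(20) if regions.nucleus[i, j]]
        mean = sum(acc) / len(acc)
        var = sum((v - mean) ** 2 for v in acc) / len(acc)  # population
        assert st.mean_nucleus == pytest.approx(mean, abs=1e-12)
        assert st.std_nucleus == pytest.approx(math.sqrt(var), abs=1e-12)


class TestColorFeatures:
    def test_constant_image_ratio_semantics(self):
        img = np.full((20, 20, 3), 100, np.uint8)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mask[8:12, 13:15] = False
        regions = CellRegions.from_nucleus(mask)
        feats = color_features(feature_channels(img), regions)
        mean_ratios = feats[0::4]
        std_ratios = feats[1::4]
        # constant planes: mean ratios 1, zero-std denominators fire the guard
        np.testing.assert_allclose(mean_ratios[mean_ratios > 0], 1.0, atol=1e-9)
        np.testing.assert_allclose(std_ratios, 0.0, atol=1e-12)

    def test_empty_roc_zeroes_roc_entries(self, rng):
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True  # convex -> empty ROC
        regions = CellRegions.from_nucleus(mask)
        feats = color_features(feature_channels(img), regions)
        np.testing.assert_array_equal(feats[2::4], 0.0)
        np.testing.assert_array_equal(feats[3::4], 0.0)

    def test_matches_channelwise_oracle(self, lymphocyte_crop):
        from wbckit.nucleus import segment_nucleus

        regions = CellRegions.from_nucleus(segment_nucleus(lymphocyte_crop.image))
        stack = feature_channels(lymphocyte_crop.image)
        feats = color_features(stack, regions)
        for i, name in enumerate(CHANNEL_NAMES):
            p = stack[name]
            nuc, hull, roc = p[regions.nucleus], p[regions.hull], p[regions.roc]
            def guard(num, den):
                return 0.0 if den < 1e-6 else num / den
            expected = [
                guard(nuc.mean(), hull.mean()),
                guard(nuc.std(), hull.std()),
                guard(roc.mean(), hull.mean()) if roc.size else 0.0,
                guard(roc.std(), hull.std()) if roc.size else 0.0,
            ]
            np.testing.assert_allclose(feats[4 * i : 4 * i + 4], expected, atol=1e-12)


class TestExtractFeatures:
    def test_vector_has_51_finite_entries(self, lymphocyte_crop):
        vec = extract_features(lymphocyte_crop.image)
        assert vec.shape == (51,)
        assert np.isfinite(vec).all()
        assert len(FEATURE_NAMES) == N_FEATURES == 51

    def test_round_nucleus_is_nearly_solid(self, lymphocyte_crop):
        vec = extract_features(lymphocyte_crop.image)
        assert vec[0] >= 0.95

    def test_reflection_invariance(self, neutrophil_crop):
        v = extract_features(neutrophil_crop.image)
        v_flip = extract_features(neutrophil_crop.image[:, ::-1])
        np.testing.assert_allclose(v, v_flip, atol=1e-6)

    def test_rotation_invariance(self, neutrophil_crop):
        v = extract_features(neutrophil_crop.image)
        v_rot = extract_features(np.rot90(neutrophil_crop.image))
        np.testing.assert_allclose(v, v_rot, atol=1e-3)

    def test_blank_image_raises_named_error(self):
        with pytest.raises(ExtractionFailedError, match="blank.png"):
            extract_features(np.full((32, 32, 3), 255, np.uint8), image_id="blank.png")

    def test_lymphocytes_more_solid_than_neutrophils(self, crop_features):
        X, y = crop_features
        assert X[y == "lymphocyte", 0].mean() > X[y == "neutrophil", 0].mean()
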