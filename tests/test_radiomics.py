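"""Feature extraction: quantization rules, hand-computed first-order
statistics, texture features against brute-force oracles, shape
geometry, per-subject extraction contracts."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stirqmri as sq
from stirqmri import radiomics
from stirqmri.radiomics import (FEATURE_CATALOG, FIRST_ORDER_NAMES,
                                GLCM_NAMES, GLZLM_NAMES, GLRLM_NAMES,
                                SHAPE_NAMES, quantize)
from oracles import (boundary_edge_perimeter, glcm_oracle, glzlm_oracle)


def qroi_from(values, n_levels):
    arr = np.asarray(values, dtype=np.float64)
    return quantize(arr, np.ones_like(arr, dtype=bool), n_levels)


class TestQuantize:
    def test_integer_ramp_is_bijective(self):
        arr = np.arange(64, dtype=float).reshape(8, 8)
        q = quantize(arr, np.ones((8, 8), bool), 64)
        assert np.array_equal(np.sort(q.grid.ravel()), np.arange(1, 65))

    def test_constant_roi_all_level_one(self):
        q = qroi_from(np.full((4, 4), 7.0), 64)
        assert np.all(q.grid == 1)

    def test_three_values_two_levels(self):
        q = qroi_from(np.array([[0.0, 10.0, 20.0]]), 2)
        assert q.grid.tolist() == [[1, 1, 2]]

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.ones((3, 3)), np.zeros((3, 3), bool))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 255, allow_nan=False), min_size=2,
                    max_size=40),
           st.integers(2, 64))
    def test_levels_span_and_cover(self, values, n_levels):
        q = qroi_from(np.asarray(values), n_levels)
        inside = q.grid[q.grid > 0]
        assert inside.min() >= 1 and inside.max() <= n_levels
        assert inside.size == len(values)


class TestFirstOrder:
    def test_hand_example_1234(self):
        f = radiomics.first_order_features(np.array([[1.0, 2, 3, 4]]),
                                           np.ones((1, 4), bool))
        assert f["CONVENTIONAL_mean"] == 2.5
        assert f["CONVENTIONAL_std"] == pytest.approx(np.sqrt(1.25))
        assert f["CONVENTIONAL_Q1"] == pytest.approx(1.75)
        assert f["CONVENTIONAL_median"] == 2.5
        assert f["CONVENTIONAL_Q3"] == pytest.approx(3.25)
        assert f["CONVENTIONAL_sum"] == 10.0
        assert f["CONVENTIONAL_MAD"] == 1.0

    def test_constant_roi_degenerate_values(self):
        f = radiomics.first_order_features(np.full((3, 3), 5.0),
                                           np.ones((3, 3), bool))
        assert f["CONVENTIONAL_mean"] == 5.0
        assert f["CONVENTIONAL_std"] == 0.0
        assert f["CONVENTIONAL_Uniformity"] == 1.0
        assert f["CONVENTIONAL_Entropy_log2"] == 0.0

    def test_two_equal_mass_levels(self):
        arr = np.array([[0.0] * 4 + [63.0] * 4])
        f = radiomics.first_order_features(arr, np.ones_like(arr, bool),
                                           n_levels=64)
        assert f["CONVENTIONAL_Uniformity"] == pytest.approx(0.5)
        assert f["CONVENTIONAL_Entropy_log2"] == pytest.approx(1.0)

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            radiomics.first_order_features(np.ones((1, 1)),
                                           np.ones((1, 1), bool))


class TestGlcm:
    def test_constant_roi_single_cell(self):
        q = qroi_from(np.full((3, 3), 2.0), 8)
        f = radiomics.glcm_features(q)
        assert f["GLCM_Energy"] == 1.0
        assert f["GLCM_Contrast"] == 0.0
        assert f["GLCM_Dissimilarity"] == 0.0
        assert f["GLCM_Entropy_log2"] == 0.0

    def test_2x2_grid_matches_pair_enumeration_oracle(self):
        q = qroi_from(np.array([[0.0, 0.0], [0.0, 1.0]]), 2)
        mine = radiomics.glcm_features(q)
        ref = glcm_oracle(q.grid, 2)
        for k in GLCM_NAMES:
            assert mine[k] == pytest.approx(ref[k], abs=1e-12), k

    def test_striped_image_vertical_correlation_is_minus_one(self):
        arr = np.tile(np.array([[0.0], [1.0]]), (2, 4))   # rows alternate
        q = quantize(arr, np.ones_like(arr, bool), 2)
        f = radiomics.glcm_features(q, offsets=[(1, 0)])
        assert f["GLCM_Correlation"] == pytest.approx(-1.0)

    def test_random_grids_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            arr = rng.integers(0, 4, size=(5, 6)).astype(float)
            mask = rng.random((5, 6)) < 0.8
            if mask.sum() < 4:
                continue
            q = quantize(arr, mask, 4)
            mine = radiomics.glcm_features(q)
            ref = glcm_oracle(q.grid, 4)
            for k in GLCM_NAMES:
                assert mine[k] == pytest.approx(ref[k], abs=1e-10), k

    def test_rotation_invariance_of_direction_average(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 8, size=(7, 7)).astype(float)
        q1 = quantize(arr, np.ones_like(arr, bool), 8)
        q2 = quantize(np.rot90(arr), np.ones_like(arr, bool), 8)
        f1 = radiomics.glcm_features(q1)
        f2 = radiomics.glcm_features(q2)
        for k in GLCM_NAMES:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k


class TestZonesAndRuns:
    def test_constant_roi_single_zone_closed_forms(self):
        n = 12
        q = qroi_from(np.full((3, 4), 9.0), 8)
        f = radiomics.glzlm_features(q)
        assert f["GLZLM_LZE"] == n ** 2
        assert f["GLZLM_ZP"] == pytest.approx(1.0 / n)
        assert f["GLZLM_GLNU"] == 1.0

    def test_checkerboard_zones_under_8_connectivity(self):
        # with 8-connected zones the two checkerboard colors each form a
        # single diagonal-linked zone of 8 pixels
        arr = np.indices((4, 4)).sum(axis=0) % 2
        q = quantize(arr.astype(float), np.ones((4, 4), bool), 2)
        f = radiomics.glzlm_features(q)
        assert f["GLZLM_LZE"] == 64.0        # two zones of size 8
        assert f["GLZLM_SZE"] == pytest.approx(1.0 / 64.0)
        assert f["GLZLM_ZP"] == pytest.approx(2.0 / 16.0)

    def test_toy_grid_matches_flood_fill_oracle(self):
        arr = np.array([[0, 0, 1, 1],
                        [0, 0, 1, 1],
                        [1, 0, 0, 1],
                        [1, 1, 0, 0]], dtype=float)
        q = quantize(arr, np.ones((4, 4), bool), 2)
        mine = radiomics.glzlm_features(q)
        ref = glzlm_oracle(q.grid, 2)
        for k in GLZLM_NAMES:
            assert mine[k] == pytest.approx(ref[k], abs=1e-12), k

    def test_random_masked_grids_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            arr = rng.integers(0, 3, size=(6, 6)).astype(float)
            mask = rng.random((6, 6)) < 0.85
            if mask.sum() < 4 or arr[mask].max() == arr[mask].min():
                continue
            q = quantize(arr, mask, 3)
            mine = radiomics.glzlm_features(q)
            ref = glzlm_oracle(q.grid, 3)
            for k in GLZLM_NAMES:
                assert mine[k] == pytest.approx(ref[k], abs=1e-12), k

    def test_glzlm_mass_balance(self, fshd_small):
        subj = fshd_small[0]
        sl = subj.slices[subj.mid_slice_index]
        roi = subj.masks[subj.mid_slice_index].labels["S_left"]
        q = quantize(sl.pixels, roi, 64)
        m = radiomics.glzlm_matrix(q)
        sizes = np.arange(1, m.shape[1] + 1)
        assert (m * sizes).sum() == roi.sum()

    def test_constant_roi_runs(self):
        q = qroi_from(np.full((2, 3), 1.0), 4)
        f = radiomics.glrlm_features(q)
        assert f["GLRLM_LGRE"] == 1.0       # single gray level 1
        assert f["GLRLM_RP"] <= 1.0
        # row direction: 2 runs of 3; column: 3 runs of 2; diagonals: runs
        # of sizes bounded by the grid -> SRE < 1 strictly
        assert 0.0 < f["GLRLM_SRE"] < 1.0


class TestShape:
    def test_square_mask_volumes(self):
        mask = np.zeros((12, 12), bool)
        mask[1:11, 1:11] = True
        f = radiomics.shape_features(mask, 1.0, 5.0)
        assert f["SHAPE_Volume_vx"] == 100
        assert f["SHAPE_Volume_mL"] == pytest.approx(0.5)

    def test_single_pixel(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        f = radiomics.shape_features(mask, 1.0, 5.0)
        assert f["SHAPE_Volume_vx"] == 1

    def test_rectangle_perimeter_equals_edge_count_oracle(self):
        mask = np.zeros((4, 5), bool)
        mask[1, 1:3] = True                  # 2x1 rectangle
        f = radiomics.shape_features(mask, 1.0, 5.0)
        assert boundary_edge_perimeter(mask) == 6
        assert f["SHAPE_Surface_mm2"] == pytest.approx(30.0)

    def test_random_masks_match_edge_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mask = rng.random((8, 8)) < 0.5
            if not mask.any():
                continue
            f = radiomics.shape_features(mask, 1.0, 5.0)
            assert f["SHAPE_Surface_mm2"] == pytest.approx(
                boundary_edge_perimeter(mask) * 5.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            radiomics.shape_features(np.zeros((3, 3), bool), 1.0, 5.0)


class TestExtraction:
    def test_catalog_is_56_split_25_26_5(self):
        assert len(FEATURE_CATALOG) == 56
        assert len(FIRST_ORDER_NAMES) == 25
        assert len(GLCM_NAMES) + len(GLZLM_NAMES) + len(GLRLM_NAMES) == 26
        assert len(SHAPE_NAMES) == 5
        cat = radiomics.load_catalog()
        json_names = (cat["first_order"] + cat["glcm"] + cat["glzlm"]
                      + cat["glrlm"] + cat["shape"])
        assert tuple(json_names) == FEATURE_CATALOG

    def test_extract_returns_complete_finite_vectors(self, fshd_small):
        feats = sq.extract_features(fshd_small[0])
        assert set(feats) == set(sq.MUSCLES)
        for vec in feats.values():
            assert tuple(vec) == FEATURE_CATALOG
            assert all(np.isfinite(v) for v in vec.values())

    def test_identical_sides_average_to_either_side(self, fshd_small):
        subj = fshd_small[1]
        idx = subj.mid_slice_index
        mset = subj.masks[idx]
        # build a subject whose right ROIs mirror the left pixels exactly
        import copy
        twin = copy.deepcopy(subj)
        sl = twin.slices[idx]
        for muscle in sq.MUSCLES:
            left = mset.labels[f"{muscle}_left"]
            right = mset.labels[f"{muscle}_right"]
            sl.pixels[right] = sl.pixels[left]
        feats = sq.extract_features(twin, idx)
        from stirqmri.radiomics import _roi_feature_vector
        for muscle in ("S", "TA"):
            left_only = _roi_feature_vector(
                sl.pixels, mset.labels[f"{muscle}_left"],
                sl.pixel_spacing, sl.slice_thickness, 64)
            for k in FEATURE_CATALOG:
                assert feats[muscle][k] == pytest.approx(left_only[k],
                                                         rel=1e-12), k

    def test_build_tables_shape_and_round_trip(self, tmp_path, fshd_small):
        tables = sq.build_feature_tables(fshd_small[:5])
        assert set(tables) == set(sq.MUSCLES)
        for df in tables.values():
            assert df.shape == (5, 58)       # 56 features + FF + wT2
            path = tmp_path / "t.csv"
            df.to_csv(path, float_format="%.17g")
            import pandas as pd
            back = pd.read_csv(path, index_col=0,
                               float_precision="round_trip")
            assert np.allclose(back.to_numpy(), df.to_numpy(), rtol=0,
                               atol=0)
            break

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sq.build_feature_tables([])
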