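"""Unit and property tests for the hair-removal pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dermokit import hair_removal as hr
from dermokit import synthetic
from tests.conftest import oracle_close, oracle_dilate, oracle_erode

small_planes = arrays(
    dtype=np.uint8, shape=(9, 9), elements=st.integers(min_value=0, max_value=255)
)


class TestStructuringElement:
    @pytest.mark.parametrize("r", [1, 2, 3, 5])
    def test_footprint_matches_bruteforce_membership(self, r):
        se = hr.StructuringElement(r)
        expected = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if (dy**2 + dx**2) ** 0.5 <= r:
                    expected[dy + r, dx + r] = True
        assert np.array_equal(se.footprint, expected)

    def test_symmetric_and_contains_origin(self):
        for r in (1, 2, 3):
            fp = hr.StructuringElement(r).footprint
            assert fp[r, r]
            assert np.array_equal(fp, fp[::-1, ::-1])

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            hr.StructuringElement(0)
        with pytest.raises(ValueError):
            hr.StructuringElement(2, metric="hamming")

    def test_r1_cross_footprint(self):
        # Euclidean r=1 is the 5-pixel cross
        assert hr.StructuringElement(1).footprint.sum() == 5


class TestSplitMerge:
    def test_constant_image_planes(self):
        img = np.empty((2, 2, 3), dtype=np.uint8)
        img[:, :, 0], img[:, :, 1], img[:, :, 2] = 10, 20, 30
        r, g, b = hr.split_channels(img)
        assert np.all(r.values == 10) and np.all(g.values == 20) and np.all(b.values == 30)
        assert (r.channel_id, g.channel_id, b.channel_id) == ("R", "G", "B")

    def test_round_trip(self, rng):
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        assert np.array_equal(hr.merge_channels(*hr.split_channels(img)), img)

    def test_plane_values_match_definition(self, rng):
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        r, _, _ = hr.split_channels(img)
        assert np.array_equal(r.values, img[:, :, 0])

    def test_rejects_wrong_dimensionality(self):
        with pytest.raises(ValueError):
            hr.split_channels(np.zeros((4, 4), dtype=np.uint8))


class TestMorphology:
    def test_close_constant_plane_unchanged(self):
        plane = np.full((7, 7), 123, dtype=np.uint8)
        assert np.array_equal(hr.morph_close(plane, hr.StructuringElement(2)), plane)

    def test_close_fills_dark_pit(self):
        plane = np.full((5, 5), 200, dtype=np.uint8)
        plane[2, 2] = 50
        closed = hr.morph_close(plane, hr.StructuringElement(1))
        assert np.all(closed == 200)

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_morphology_matches_oracle(self, rng, r):
        for _ in range(25):
            plane = rng.integers(0, 256, size=(9, 9), dtype=np.uint8)
            se = hr.StructuringElement(r)
            assert np.array_equal(hr.dilate(plane, se), oracle_dilate(plane, r))
            assert np.array_equal(hr.erode(plane, se), oracle_erode(plane, r))
            assert np.array_equal(hr.morph_close(plane, se), oracle_close(plane, r))

    @given(plane=small_planes, r=st.integers(min_value=1, max_value=3))
    @settings(max_examples=40, deadline=None)
    def test_closing_extensive_and_idempotent(self, plane, r):
        se = hr.StructuringElement(r)
        closed = hr.morph_close(plane, se)
        assert np.all(closed >= plane)
        assert np.array_equal(hr.morph_close(closed, se), closed)

    def test_dilate_zero_plane(self):
        plane = np.zeros((6, 6), dtype=np.uint8)
        assert np.array_equal(hr.dilate(plane, hr.StructuringElement(2)), plane)

    def test_dilate_single_pixel_cross(self):
        plane = np.zeros((5, 5), dtype=np.uint8)
        plane[2, 2] = 150
        dil = hr.dilate(plane, hr.StructuringElement(1))
        expected = np.zeros((5, 5), dtype=np.int64)
        for y, x in [(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)]:
            expected[y, x] = 150
        assert np.array_equal(dil, expected)


class TestSubtractThreshold:
    def test_subtract_identical_is_zero(self, rng):
        plane = rng.integers(0, 256, size=(6, 6), dtype=np.uint8)
        assert np.all(hr.subtract(plane, plane) == 0)

    def test_subtract_elementwise(self):
        orig = np.full((4, 4), 200, dtype=np.uint8)
        orig[1, 1] = 50
        closed = np.full((4, 4), 200, dtype=np.uint8)
        diff = hr.subtract(closed, orig)
        expected = np.zeros((4, 4), dtype=np.int64)
        expected[1, 1] = 150
        assert np.array_equal(diff, expected)

    def test_subtract_shape_mismatch(self):
        with pytest.raises(ValueError):
            hr.subtract(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_closing_difference_nonnegative(self, rng):
        for _ in range(100):
            plane = rng.integers(0, 256, size=(7, 7), dtype=np.uint8)
            closed = hr.morph_close(plane, hr.StructuringElement(2))
            assert np.all(hr.subtract(closed, plane) >= 0)

    def test_threshold_all_below_K(self):
        plane = np.arange(41, dtype=np.int64).reshape(1, -1)  # 0..40, all <= 40
        assert np.all(hr.threshold_zero(plane, 40) == 0)

    def test_threshold_value_above_K_retained(self):
        plane = np.array([[150]], dtype=np.int64)
        assert hr.threshold_zero(plane, 40)[0, 0] == 150

    def test_threshold_value_exactly_K_zeroed(self):
        # strict inequality: P > K retained, P <= K zeroed
        plane = np.array([[40]], dtype=np.int64)
        assert hr.threshold_zero(plane, 40)[0, 0] == 0

    def test_threshold_idempotent(self, rng):
        plane = rng.integers(0, 256, size=(8, 8)).astype(np.int64)
        once = hr.threshold_zero(plane, 40)
        assert np.array_equal(hr.threshold_zero(once, 40), once)

    def test_threshold_monotone_in_K(self, rng):
        # raising K never grows the detected support
        plane = rng.integers(0, 256, size=(10, 10)).astype(np.int64)
        prev = hr.extract_mask(hr.threshold_zero(plane, 10))
        for K in (40, 80, 160):
            cur = hr.extract_mask(hr.threshold_zero(plane, K))
            assert np.all(prev | cur == prev)
            prev = cur


class TestExtractMask:
    def test_zero_plane_all_false(self):
        assert not hr.extract_mask(np.zeros((5, 5))).any()

    def test_cross_support(self):
        plane = np.zeros((5, 5), dtype=np.int64)
        plane[2, 2] = 150
        mask = hr.extract_mask(hr.dilate(plane, hr.StructuringElement(1)))
        assert mask.sum() == 5
        assert mask[2, 2] and mask[1, 2] and mask[3, 2] and mask[2, 1] and mask[2, 3]

    def test_cardinality_equals_nonzeros(self, rng):
        plane = rng.integers(0, 3, size=(8, 8)).astype(np.int64)
        assert hr.extract_mask(plane).sum() == np.count_nonzero(plane)


class TestInpaint:
    def test_empty_mask_bit_exact(self, rng):
        plane = rng.integers(0, 256, size=(6, 6), dtype=np.uint8)
        out = hr.inpaint_laplace(plane, np.zeros((6, 6), dtype=bool))
        assert np.array_equal(out, plane)

    def test_constant_surround_plus_mask(self):
        plane = np.full((9, 9), 200, dtype=np.uint8)
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 2:7] = True
        mask[2:7, 4] = True
        out = hr.inpaint_laplace(plane, mask)
        assert np.allclose(out[mask], 200.0)

    def test_linear_ramp_recovered(self):
        # harmonic extension of a linear field is the linear field
        ramp = np.tile(np.arange(0, 200, 10, dtype=np.float64), (12, 1))
        mask = np.zeros(ramp.shape, dtype=bool)
        mask[:, 7] = True
        damaged = ramp.copy()
        damaged[mask] = 0
        out = hr.inpaint_laplace(damaged, mask)
        assert np.max(np.abs(out[:, 7] - ramp[:, 7])) < 0.5

    def test_harmonicity_and_boundary_fidelity(self, rng):
        plane = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:9, 5:15] = True
        out = hr.inpaint_laplace(plane, mask)
        assert np.array_equal(out[~mask], plane[~mask].astype(np.float64))
        # interior harmonic condition
        for y in range(6, 8):
            for x in range(6, 14):
                nbrs = [out[y - 1, x], out[y + 1, x], out[y, x - 1], out[y, x + 1]]
                assert abs(out[y, x] - np.mean(nbrs)) <= 1e-3

    def test_full_mask_raises(self):
        with pytest.raises(ValueError):
            hr.inpaint_laplace(np.zeros((4, 4)), np.ones((4, 4), dtype=bool))

    def test_matches_dense_solve_oracle(self, rng):
        # independent dense linear-system route
        plane = rng.integers(0, 256, size=(8, 8)).astype(np.float64)
        mask = np.zeros((8, 8), dtype=bool)
        mask[3:5, 2:6] = True
        out = hr.inpaint_laplace(plane, mask)
        ys, xs = np.nonzero(mask)
        idx = {(y, x): i for i, (y, x) in enumerate(zip(ys, xs))}
        A = np.zeros((len(ys), len(ys)))
        b = np.zeros(len(ys))
        for (y, x), i in idx.items():
            nbrs = [(y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)]
            nbrs = [(ny, nx) for ny, nx in nbrs if 0 <= ny < 8 and 0 <= nx < 8]
            A[i, i] = len(nbrs)
            for q in nbrs:
                if q in idx:
                    A[i, idx[q]] = -1
                else:
                    b[i] += plane[q]
        expected = np.linalg.solve(A, b)
        assert np.allclose(out[mask], expected, atol=1e-8)


class TestRemoveHair:
    def test_constant_image_noop(self):
        img = np.full((32, 32, 3), 180, dtype=np.uint8)
        result = hr.remove_hair(img)
        assert np.array_equal(result.image, img)
        assert not result.merged_mask.any()
        for m in result.masks.values():
            assert not m.any()

    def test_synthetic_recall_and_improvement(self):
        spec = synthetic.LesionImageSpec(noise_sd=3.0, seed=7)
        clean = synthetic.generate_lesion_image(spec)
        hairy, truth = synthetic.overlay_hair(
            clean, synthetic.HairOverlaySpec(n_strokes=5, stroke_darkness=120, seed=8)
        )
        result = hr.remove_hair(hairy)
        recall = (result.merged_mask & truth).sum() / truth.sum()
        assert recall >= 0.95
        mae_clean = np.abs(result.image[truth].astype(float) - clean[truth]).mean()
        mae_hairy = np.abs(hairy[truth].astype(float) - clean[truth]).mean()
        assert mae_clean < mae_hairy

    def test_pixels_outside_mask_unchanged(self):
        spec = synthetic.LesionImageSpec(noise_sd=2.0, seed=3)
        img, _ = synthetic.overlay_hair(
            synthetic.generate_lesion_image(spec), synthetic.HairOverlaySpec(seed=4)
        )
        result = hr.remove_hair(img)
        assert np.array_equal(result.image[~result.merged_mask], img[~result.merged_mask])

    def test_intermediates_on_request(self):
        img = np.full((16, 16, 3), 100, dtype=np.uint8)
        assert hr.remove_hair(img).intermediates is None
        inter = hr.remove_hair(img, keep_intermediates=True).intermediates
        assert set(inter) == {"R", "G", "B"}
        assert np.all(inter["R"].difference >= 0)

    def test_raising_r2_never_shrinks_mask(self):
        spec = synthetic.LesionImageSpec(noise_sd=3.0, seed=11)
        img, _ = synthetic.overlay_hair(
            synthetic.generate_lesion_image(spec), synthetic.HairOverlaySpec(seed=12)
        )
        prev = hr.remove_hair(img, hr.HairRemovalConfig(r2=1)).merged_mask
        for r2 in (2, 3):
            cur = hr.remove_hair(img, hr.HairRemovalConfig(r2=r2)).merged_mask
            assert np.all(prev <= cur)
            prev = cur

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hr.HairRemovalConfig(r1=0)
        with pytest.raises(ValueError):
            hr.HairRemovalConfig(threshold=300)
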