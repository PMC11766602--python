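import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ipcc_ar as ia
from ipcc_ar.errors import (
    DegenerateGeometryError,
    ParameterError,
    RegistrationError,
)
from ipcc_ar.ipcc import (
    IPCCConfig,
    PatchCell,
    PatchMatch,
    estimate_rotation_scaling,
    estimate_translation,
    ipcc_register,
    make_patch_grid,
    relative_change,
    select_patch_pair,
    warp,
)
from ipcc_ar.transform import SimilarityTransform


def match(i, j, cA, cB, score, size=64):
    cell = PatchCell(i=i, j=j, x=int(cA[0]), y=int(cA[1]), w=size, h=size)
    return PatchMatch(patch=cell, corner_A=cA, corner_B=cB, score=score)


class TestPatchGrid:
    def test_256_grid_of_4_gives_16_64px_patches(self):
        grid = make_patch_grid(np.zeros((256, 256)), 4)
        assert len(grid.patches) == 16
        corners = {(c.x, c.y) for c in grid.patches}
        assert corners == {(x, y) for x in (0, 64, 128, 192) for y in (0, 64, 128, 192)}
        assert all(c.w == 64 and c.h == 64 for c in grid.patches)

    def test_n1_is_whole_image(self):
        grid = make_patch_grid(np.zeros((100, 80)), 1)
        (cell,) = grid.patches
        assert (cell.x, cell.y, cell.w, cell.h) == (0, 0, 80, 100)

    def test_remainder_pixels_excluded(self):
        grid = make_patch_grid(np.zeros((100, 100)), 3)
        assert len(grid.patches) == 9
        assert all(c.w == 33 and c.h == 33 for c in grid.patches)
        assert max(c.x + c.w for c in grid.patches) == 99

    def test_too_small_patches_rejected(self):
        with pytest.raises(ParameterError):
            make_patch_grid(np.zeros((10, 10)), 3)  # 3x3 px < 8 px minimum


class TestSelectPatchPair:
    def test_two_best_above_threshold(self):
        ms = [
            match(0, 0, (0.0, 0.0), (1.0, 0.0), 0.9),
            match(0, 1, (200.0, 0.0), (201.0, 0.0), 0.8),
            match(1, 0, (0.0, 200.0), (0.0, 200.0), 0.2),
        ]
        p1, p2 = select_patch_pair(ms, t=0.3, min_separation=50)
        assert p1.score == 0.9 and p2.score == 0.8

    def test_all_below_threshold_fails(self):
        ms = [match(0, 0, (0.0, 0.0), (0.0, 0.0), 0.1)] * 3
        with pytest.raises(RegistrationError):
            select_patch_pair(ms, t=0.3, min_separation=10)

    def test_separation_forces_next_eligible(self):
        ms = [
            match(0, 0, (0.0, 0.0), (0.0, 0.0), 0.9),
            match(0, 1, (10.0, 0.0), (10.0, 0.0), 0.8),  # too close to best
            match(1, 0, (0.0, 200.0), (0.0, 200.0), 0.7),
        ]
        p1, p2 = select_patch_pair(ms, t=0.3, min_separation=100)
        assert p1.score == 0.9 and p2.score == 0.7


class TestTransformEstimation:
    def test_equal_displacement_vectors_give_identity_rotation(self):
        p1 = match(0, 0, (10.0, 10.0), (10.0, 10.0), 1.0)
        p2 = match(0, 1, (50.0, 30.0), (50.0, 30.0), 1.0)
        t = estimate_rotation_scaling(p1, p2)
        assert np.allclose(t.matrix, np.eye(3), atol=1e-12)

    def test_quarter_turn_case(self):
        # a = (1, 0), b = (0, 1): rotation +pi/2 (y-down), unit scale
        p1 = match(0, 0, (0.0, 0.0), (0.0, 0.0), 1.0)
        p2 = match(0, 1, (1.0, 0.0), (0.0, 1.0), 1.0)
        t = estimate_rotation_scaling(p1, p2)
        assert t.theta == pytest.approx(np.pi / 2)
        assert t.scale == pytest.approx(1.0)

    def test_pure_doubling_gives_scale_two(self):
        p1 = match(0, 0, (0.0, 0.0), (0.0, 0.0), 1.0)
        p2 = match(0, 1, (3.0, 4.0), (6.0, 8.0), 1.0)
        t = estimate_rotation_scaling(p1, p2)
        assert t.theta == pytest.approx(0.0)
        assert t.scale == pytest.approx(2.0)

    def test_translation_from_corner_displacement(self):
        p1 = match(0, 0, (10.0, 20.0), (15.0, 25.0), 1.0)
        t = estimate_translation(p1)
        assert np.allclose(t.apply([[10.0, 20.0]]), [[15.0, 25.0]])

    def test_coincident_points_degenerate(self):
        p1 = match(0, 0, (5.0, 5.0), (0.0, 0.0), 1.0)
        p2 = match(0, 1, (5.0, 5.0), (9.0, 9.0), 1.0)
        with pytest.raises(DegenerateGeometryError):
            estimate_rotation_scaling(p1, p2)

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_composition_maps_both_correspondences_exactly(self, data):
        f = st.floats(-100.0, 100.0, allow_nan=False)
        c1a = np.array([data.draw(f), data.draw(f)])
        c2a = c1a + np.array([data.draw(f), data.draw(f)])
        c1b = np.array([data.draw(f), data.draw(f)])
        c2b = c1b + np.array([data.draw(f), data.draw(f)])
        if np.linalg.norm(c2a - c1a) < 1e-3 or np.linalg.norm(c2b - c1b) < 1e-3:
            return
        p1 = match(0, 0, tuple(c1a), tuple(c1b), 1.0)
        p2 = match(0, 1, tuple(c2a), tuple(c2b), 1.0)
        T = estimate_translation(p1) @ estimate_rotation_scaling(p1, p2)
        mapped = T.apply(np.vstack([c1a, c2a]))
        assert np.allclose(mapped, np.vstack([c1b, c2b]), atol=1e-9)


class TestRelativeChange:
    def test_identical_matrices_give_zero(self):
        t = SimilarityTransform.from_params(0.1, 1.05, (3, 4))
        assert relative_change(t, t) == 0.0

    def test_doubling_every_element_gives_half(self):
        a = SimilarityTransform(np.array([[1.0, 0, 2], [0, 1.0, 3], [0, 0, 1]]))
        # current = 2x previous on included elements -> |old-new|/|new| = 0.5
        b = SimilarityTransform(np.array([[2.0, 0, 4], [0, 2.0, 6], [0, 0, 1]]))
        # homogeneous-row 1 changes from 1 to 1 (excluded zeros stay zero)
        delta = relative_change(a, b)
        # included: four doubled elements (0.5 each) + bottom-row 1 (0.0)
        assert delta == pytest.approx((4 * 0.5 + 0.0) / 5)

    def test_excluded_zero_elements_do_not_contribute(self):
        a = SimilarityTransform.identity()
        b = SimilarityTransform.identity()
        assert relative_change(a, b) == 0.0


class TestWarp:
    def test_identity_returns_input(self, vessel_tree):
        out = warp(vessel_tree, SimilarityTransform.identity())
        assert np.array_equal(out, vessel_tree)

    def test_integer_translation_shifts_content(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[4, 3] = 1
        out = warp(img, SimilarityTransform.translation(5, 0))
        assert out[4, 8] == 1 and out[:, :5].sum() == 0

    def test_roundtrip_recovers_interior(self, rng):
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random((64, 64)), 2.0)  # band-limited content
        g = SimilarityTransform.from_params(0.1, 1.02, (3.0, -2.0), pivot=(32, 32))
        back = warp(warp(img, g), g.inverse())
        interior = np.s_[10:54, 10:54]
        assert np.abs(back[interior] - img[interior]).mean() < 0.02


class TestIpccRegister:
    def test_self_registration_is_identity(self, vessel_skeleton):
        res = ipcc_register(vessel_skeleton, vessel_skeleton)
        assert res.converged
        assert np.abs(res.transform.matrix - np.eye(3)).max() < 1e-3

    def test_empty_reference_fails(self, vessel_skeleton):
        empty = np.zeros_like(vessel_skeleton)
        with pytest.raises(RegistrationError):
            ipcc_register(empty, vessel_skeleton)

    def test_known_transform_recovered(self, small_fixture_pairs):
        A, B, truth = small_fixture_pairs[0]
        res = ipcc_register(A, B)
        assert ia.reprojection_error(A, res.transform, truth) <= 2.0

    def test_delta_decreases_on_self_registration(self, vessel_skeleton):
        cfg = IPCCConfig(max_iterations=2, delta_tol=0.0)
        res = ipcc_register(vessel_skeleton, vessel_skeleton, cfg)
        if res.K >= 2:
            assert res.deltas[1] <= res.deltas[0]

    def test_iteration_cap_respected(self, small_fixture_pairs):
        A, B, _ = small_fixture_pairs[1]
        res = ipcc_register(A, B, IPCCConfig(max_iterations=2, delta_tol=0.0))
        assert res.K <= 2
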