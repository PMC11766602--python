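import numpy as np
import pytest

import ipcc_ar as ia
from ipcc_ar.errors import GenerationError, ParameterError
from ipcc_ar.synthetic import (
    DENSITY_BAND,
    VesselTreeParams,
    add_occlusion,
    generate_vessel_tree,
    make_fixture_pair,
    reprojection_error,
)


class TestGenerateVesselTree:
    def test_deterministic_under_seed(self):
        a = generate_vessel_tree(VesselTreeParams(seed=11))
        b = generate_vessel_tree(VesselTreeParams(seed=11))
        assert np.array_equal(a, b)

    def test_distinct_seeds_differ(self):
        a = generate_vessel_tree(VesselTreeParams(seed=1))
        b = generate_vessel_tree(VesselTreeParams(seed=2))
        assert not np.array_equal(a, b)

    def test_density_band_over_many_seeds(self):
        lo, hi = DENSITY_BAND
        for seed in range(20):
            frac = generate_vessel_tree(VesselTreeParams(seed=seed)).mean()
            assert lo <= frac <= hi

    def test_depth_zero_stubs_fail_density(self):
        with pytest.raises(GenerationError):
            generate_vessel_tree(
                VesselTreeParams(seed=0, max_depth=0, branch_prob=0.0)
            )

    def test_mask_is_binary(self):
        m = generate_vessel_tree(VesselTreeParams(seed=3))
        assert set(np.unique(m)) <= {0, 1}


class TestAddOcclusion:
    def test_zero_width_unchanged(self, vessel_tree):
        out = add_occlusion(vessel_tree, angle=0.5, width_px=0, fraction_target=0.2)
        assert np.array_equal(out, vessel_tree)

    def test_removal_only_contract(self, vessel_tree):
        out = add_occlusion(vessel_tree, angle=1.1, width_px=40, fraction_target=0.3)
        assert np.all(vessel_tree[out > 0] == 1)  # output subset of input

    def test_target_fraction_reached_over_seeds(self):
        for seed in range(10):
            m = generate_vessel_tree(VesselTreeParams(seed=seed))
            out = add_occlusion(m, angle=0.7, width_px=31, fraction_target=0.2)
            removed = 1 - out.sum() / m.sum()
            assert 0.15 <= removed <= 0.25

    def test_unreachable_fraction_warns(self, vessel_tree):
        with pytest.warns(UserWarning):
            add_occlusion(vessel_tree, angle=0.0, width_px=1, fraction_target=0.5)

    def test_fraction_out_of_range(self, vessel_tree):
        with pytest.raises(ParameterError):
            add_occlusion(vessel_tree, angle=0.0, width_px=10, fraction_target=0.7)


class TestMakeFixturePair:
    def test_identity_motion_gives_equal_pair(self):
        pair = make_fixture_pair(seed=4)
        assert np.array_equal(pair.fixed, pair.moving)

    def test_truth_maps_foreground_onto_moving(self):
        pair = make_fixture_pair(seed=5, theta=0.15, scale=1.05, d=(8.0, -5.0))
        ys, xs = np.nonzero(pair.fixed)
        rng = np.random.default_rng(0)
        sel = rng.choice(len(xs), size=50, replace=False)
        pts = np.column_stack([xs[sel], ys[sel]]).astype(float)
        mapped = pair.truth.apply(pts)
        h, w = pair.moving.shape
        hits = 0
        checked = 0
        for mx, my in mapped:
            xi, yi = int(round(mx)), int(round(my))
            if 1 <= xi < w - 1 and 1 <= yi < h - 1:
                checked += 1
                # within 1 px of a moving-map foreground pixel
                if pair.moving[yi - 1 : yi + 2, xi - 1 : xi + 2].any():
                    hits += 1
        assert checked > 0 and hits / checked > 0.95

    def test_truth_inverse_roundtrip(self):
        pair = make_fixture_pair(seed=6, theta=0.1, scale=0.95, d=(3.0, 2.0))
        composed = pair.truth @ pair.truth.inverse()
        assert np.allclose(composed.matrix, np.eye(3), atol=1e-9)

    def test_extreme_occlusion_refused(self):
        with pytest.raises(ParameterError):
            make_fixture_pair(seed=0, occlusion_fraction=0.95)

    def test_illumination_variant_only_affects_gray(self):
        pair = make_fixture_pair(seed=7, illumination=(0.8, 0.1))
        assert pair.moving_gray is not None
        assert pair.moving_gray.min() >= 0 and pair.moving_gray.max() <= 1
        assert set(np.unique(pair.moving)) <= {0, 1}


def test_reprojection_error_zero_for_equal_transforms(vessel_tree):
    t = ia.SimilarityTransform.from_params(0.1, 1.02, (4.0, 1.0), pivot=(128, 128))
    assert reprojection_error(vessel_tree, t, t) == 0.0


def test_reprojection_error_matches_translation_magnitude(vessel_tree):
    a = ia.SimilarityTransform.identity()
    b = ia.SimilarityTransform.translation(3.0, 4.0)
    assert reprojection_error(vessel_tree, a, b) == pytest.approx(5.0)
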