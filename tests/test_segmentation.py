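import numpy as np
import pytest

from ipcc_ar.errors import ParameterError
from ipcc_ar.metrics import evaluate_masks
from ipcc_ar.preprocessing import binarize
from ipcc_ar.segmentation import (
    AugmentConfig,
    TrainConfig,
    UNet,
    UNetSpec,
    augment_pair,
    build_segmenter,
    predict_vessels,
    train_segmenter,
)
from ipcc_ar.segmentation.data import synthetic_training_pairs


@pytest.fixture(scope="module")
def tiny_pairs():
    return synthetic_training_pairs(2, size=64, seed=3)


@pytest.fixture(scope="module")
def tiny_model(tiny_pairs):
    spec = UNetSpec(input_size=(64, 64))
    model, losses = train_segmenter(
        tiny_pairs, spec, TrainConfig(epochs=30, seed=0, augment=None)
    )
    return model, losses


class TestBuildSegmenter:
    def test_output_shape_and_range(self):
        model = build_segmenter(UNetSpec(input_size=(64, 64)), seed=0)
        x = np.random.default_rng(0).random((3, 64, 64))
        out = model.predict(x)
        assert out.shape == (64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_divisibility_enforced(self):
        with pytest.raises(ParameterError):
            UNetSpec(input_size=(100, 100))  # not divisible by 2^3
        model = build_segmenter(UNetSpec(input_size=(64, 64)))
        with pytest.raises(ParameterError):
            model.predict(np.zeros((3, 100, 100)))

    def test_deep_supervision_heads_at_decoder_levels(self):
        model = build_segmenter(UNetSpec(input_size=(64, 64)))
        main, aux = model.forward(np.zeros((3, 64, 64)), train=True)
        assert main.shape == (1, 64, 64)
        assert [a.shape for a in aux] == [(1, 16, 16), (1, 32, 32)]


class TestAugmentPair:
    def test_zero_ranges_are_identity(self, tiny_pairs):
        img, mask = tiny_pairs[0]
        cfg = AugmentConfig(
            rotation_deg=0, flip_lr=False, flip_ud=False, shear_deg=0,
            brightness=0, contrast=0,
        )
        img2, mask2 = augment_pair(img, mask, cfg, seed=5)
        assert np.array_equal(img2, img) and np.array_equal(mask2, mask)

    def test_deterministic_under_seed(self, tiny_pairs):
        img, mask = tiny_pairs[0]
        cfg = AugmentConfig()
        a = augment_pair(img, mask, cfg, seed=9)
        b = augment_pair(img, mask, cfg, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_geometry_shared_between_image_and_mask(self):
        # bright blob on the image exactly where the mask foreground is;
        # after augmentation the two must still coincide
        img = np.zeros((32, 32))
        mask = np.zeros((32, 32), dtype=np.uint8)
        img[4:9, 20:26] = 1.0
        mask[4:9, 20:26] = 1
        cfg = AugmentConfig(rotation_deg=90, brightness=0, contrast=0)
        img2, mask2 = augment_pair(img, mask, cfg, seed=2)
        if mask2.sum() == 0:
            pytest.skip("blob rotated out of frame")
        ys, xs = np.nonzero(mask2)
        cy_mask, cx_mask = ys.mean(), xs.mean()
        total = img2.sum()
        cy_img = (np.arange(32)[:, None] * img2).sum() / total
        cx_img = (np.arange(32)[None, :] * img2).sum() / total
        assert abs(cy_img - cy_mask) < 1.5 and abs(cx_img - cx_mask) < 1.5

    def test_mask_stays_binary(self, tiny_pairs):
        _, mask = tiny_pairs[0]
        _, mask2 = augment_pair(np.zeros(mask.shape), mask, AugmentConfig(), seed=1)
        assert set(np.unique(mask2)) <= {0, 1}


class TestTraining:
    def test_loss_decreases(self, tiny_model):
        _, losses = tiny_model
        assert losses[-1] < losses[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ParameterError):
            train_segmenter([], UNetSpec(input_size=(64, 64)))

    def test_training_reproducible_under_seed(self, tiny_pairs):
        spec = UNetSpec(input_size=(64, 64))
        cfg = TrainConfig(epochs=3, seed=4, augment=None)
        _, l1 = train_segmenter(tiny_pairs, spec, cfg)
        _, l2 = train_segmenter(tiny_pairs, spec, cfg)
        assert l1 == l2

    def test_checkpoint_roundtrip_bit_identical(self, tiny_model, tiny_pairs, tmp_path):
        model, _ = tiny_model
        model.save(tmp_path / "ckpt.npz")
        reloaded = UNet.load(tmp_path / "ckpt.npz")
        img = tiny_pairs[0][0]
        assert np.array_equal(
            predict_vessels(model, img), predict_vessels(reloaded, img)
        )


class TestPredictVessels:
    def test_output_matches_frame_size_and_range(self, tiny_model, rng):
        model, _ = tiny_model
        frame = rng.random((48, 40))
        prob = predict_vessels(model, frame)
        assert prob.shape == (48, 40)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_deterministic(self, tiny_model, rng):
        model, _ = tiny_model
        frame = rng.random((32, 32))
        assert np.array_equal(
            predict_vessels(model, frame), predict_vessels(model, frame)
        )

    def test_overfit_prediction_matches_mask(self, tiny_pairs):
        # short overfit run on two tiny images reaches high train Dice
        spec = UNetSpec(input_size=(64, 64))
        model, _ = train_segmenter(
            tiny_pairs, spec, TrainConfig(epochs=120, seed=0, augment=None)
        )
        dices = [
            evaluate_masks(binarize(predict_vessels(model, img), 0.5), m).dice
            for img, m in tiny_pairs
        ]
        assert np.mean(dices) > 0.8
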