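"""Overfit the small deeply-supervised U-Net on synthetic fundus pairs.

Four 64x64 image/mask pairs, batch size one. The network is tiny (three
levels, three channels at the first convolution) but has enough capacity to
memorize four images — the standard smoke test that the architecture, loss
and optimizer are wired correctly.
"""

import numpy as np

from ipcc_ar import binarize, evaluate_masks
from ipcc_ar.segmentation import (
    TrainConfig,
    UNetSpec,
    predict_vessels,
    train_segmenter,
)
from ipcc_ar.segmentation.data import synthetic_training_pairs

pairs = synthetic_training_pairs(4, size=64, seed=0)
model, losses = train_segmenter(
    pairs,
    UNetSpec(input_size=(64, 64)),
    TrainConfig(epochs=200, batch_size=1, seed=0, augment=None),
)
print(f"soft-Dice loss: {losses[0]:.3f} (epoch 1) -> {losses[-1]:.3f} (epoch 200)")
dices = [
    evaluate_masks(binarize(predict_vessels(model, img), 0.5), mask).dice
    for img, mask in pairs
]
print(f"training Dice per pair: {np.round(dices, 3)}  mean {np.mean(dices):.3f}")
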