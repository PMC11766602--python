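"""Deeply-supervised U-Net for retinal vessel segmentation, in NumPy.

The network follows the encoder-decoder U-Net layout at small scale: three
resolution levels and three channels at the first convolution, with channel
width doubling per level. During training, auxiliary 1x1-convolution heads
("deep supervision") predict the vessel map at each decoder resolution; each
head contributes equally to a soft Dice loss, which matches the Dice metric
the model is evaluated on. Inference uses only the full-resolution head.

Training runs on the CPU with batch size one; the model is small enough
(a few thousand parameters) that this is fast. Weights serialize to an
``.npz`` checkpoint plus a JSON sidecar describing the architecture and
training configuration; a reloaded model reproduces predictions bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from ..errors import ParameterError
from . import _autograd as ag

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "UNet",
    "build_segmenter",
    "train_segmenter",
    "predict_vessels",
    "load_segmenter",
]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture of the segmenter.

    ``depth`` encoder/decoder levels with ``base_channels`` at the first
    convolution, doubling per level; inputs must be divisible by
    ``2**depth`` in both spatial dimensions.
    """

    depth: int = 3
    base_channels: int = 3
    in_channels: int = 3
    out_channels: int = 1
    input_size: tuple[int, int] = (256, 256)
    deep_supervision: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.out_channels != 1:
            raise ParameterError("only single-channel (vessel) output supported")
        f = 2**self.depth
        h, w = self.input_size
        if h % f or w % f:
            raise ParameterError(
                f"input size {self.input_size} must be divisible by 2^depth = {f}"
            )


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the random training augmentations (0 disables each)."""

    rotation_deg: float = 15.0
    flip_lr: bool = True
    flip_ud: bool = True
    shear_deg: float = 5.0
    brightness: float = 0.1
    contrast: float = 0.1


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 1
    learning_rate: float = 2e-3
    seed: int = 0
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be >= 1")


class _Adam:
    def __init__(self, params: list[ag.Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class UNet:
    """Weight container + forward pass. Build via :func:`build_segmenter`."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, ag.Tensor] = {}
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        enc_in = spec.in_channels
        # encoder: two 3x3 convs per level; channels double per level
        for lvl in range(spec.depth):
            co = c * 2**lvl
            self._conv(rng, f"enc{lvl}a", co, enc_in)
            self._conv(rng, f"enc{lvl}b", co, co)
            enc_in = co
        cb = c * 2**spec.depth
        self._conv(rng, "bota", cb, enc_in)
        self._conv(rng, "botb", cb, cb)
        # decoder: upsample, concat skip, two convs; aux head per level
        up_in = cb
        for lvl in reversed(range(spec.depth)):
            co = c * 2**lvl
            self._conv(rng, f"dec{lvl}a", co, up_in + co)
            self._conv(rng, f"dec{lvl}b", co, co)
            self._conv(rng, f"head{lvl}", spec.out_channels, co, k=1)
            up_in = co

    def _conv(self, rng, name: str, co: int, ci: int, k: int = 3) -> None:
        fan_in = ci * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(co, ci, k, k))
        self.params[f"{name}.w"] = ag.Tensor(w, requires_grad=True)
        self.params[f"{name}.b"] = ag.Tensor(np.zeros(co), requires_grad=True)

    def _block(self, x: ag.Tensor, name: str) -> ag.Tensor:
        p = self.params
        x = ag.relu(ag.conv2d(x, p[f"{name}a.w"], p[f"{name}a.b"]))
        return ag.relu(ag.conv2d(x, p[f"{name}b.w"], p[f"{name}b.b"]))

    def forward(self, image: np.ndarray, train: bool = False):
        """Probability map(s) for a (C, H, W) input in [0, 1].

        Returns the full-resolution sigmoid output; with ``train=True``,
        returns ``(main, [aux_level_1, aux_level_2, ...])`` where auxiliary
        maps live at coarser decoder resolutions (finest first is the main
        head).
        """
        spec = self.spec
        h, w = image.shape[1:]
        if h % 2**spec.depth or w % 2**spec.depth:
            raise ParameterError(
                f"input {w}x{h} not divisible by 2^depth = {2**spec.depth}"
            )
        p = self.params
        # center [0, 1] intensities to [-1, 1]; with ReLU activations and only
        # three first-layer channels, zero-mean inputs train far more reliably
        x = ag.Tensor((np.asarray(image, dtype=float) - 0.5) * 2.0)
        skips = []
        for lvl in range(spec.depth):
            x = self._block(x, f"enc{lvl}")
            skips.append(x)
            x = ag.maxpool2(x)
        x = self._block(x, "bot")
        aux: list[ag.Tensor] = []
        main: ag.Tensor | None = None
        for lvl in reversed(range(spec.depth)):
            x = ag.concat(ag.upsample2(x), skips[lvl])
            x = self._block(x, f"dec{lvl}")
            head = ag.sigmoid(
                ag.conv2d(x, p[f"head{lvl}.w"], p[f"head{lvl}.b"])
            )
            if lvl == 0:
                main = head
            elif spec.deep_supervision:
                aux.append(head)
        if train:
            return main, aux
        return main

    def predict(self, image: np.ndarray) -> np.ndarray:
        """(C, H, W) input -> (H, W) vessel-probability map."""
        return self.forward(image).data[0]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path, train_config: TrainConfig | None = None) -> None:
        path = Path(path)
        np.savez(path, **{k: t.data for k, t in self.params.items()})
        sidecar = {
            "spec": asdict(self.spec),
            "train_config": asdict(train_config) if train_config else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        sd = sidecar["spec"]
        sd["input_size"] = tuple(sd["input_size"])
        model = cls(UNetSpec(**sd))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            for k in model.params:
                model.params[k].data = data[k].astype(float)
        return model


def build_segmenter(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Construct an untrained segmenter with seeded He-initialized weights."""
    return UNet(spec or UNetSpec(), seed=seed)


def load_segmenter(path: str | Path) -> UNet:
    return UNet.load(path)


def _downsample_mask(mask: np.ndarray, times: int) -> np.ndarray:
    """2x2 max-pool a {0,1} mask repeatedly (keeps thin vessels present)."""
    m = mask
    for _ in range(times):
        h, w = m.shape
        m = m.reshape(h // 2, 2, w // 2, 2).max(axis=(1, 3))
    return m


def train_segmenter(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    spec: UNetSpec | None = None,
    config: TrainConfig | None = None,
) -> tuple[UNet, list[float]]:
    """Train on (image, mask) pairs; returns the model and per-epoch losses.

    ``image`` is (H, W) gray or (H, W, 3) RGB in [0, 1]; ``mask`` is a {0,1}
    array of the same spatial size. The loss is soft Dice averaged over the
    main head and (downsampled-target) auxiliary heads. Deterministic under
    ``config.seed``.
    """
    from .augment import augment_pair  # local import to avoid cycle

    if not pairs:
        raise ParameterError("training set is empty")
    spec = spec or UNetSpec()
    config = config or TrainConfig()
    model = build_segmenter(spec, seed=config.seed)
    opt = _Adam(list(model.params.values()), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    losses: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        for idx in order:
            image, mask = pairs[idx]
            if config.augment is not None:
                image, mask = augment_pair(
                    image, mask, config.augment, seed=int(rng.integers(2**31))
                )
            x = _to_chw(image, spec.in_channels)
            main, aux = model.forward(x, train=True)
            heads = [(main, np.asarray(mask))]
            for a in aux:
                times = int(np.log2(mask.shape[0] // a.shape[1]))
                heads.append((a, _downsample_mask(np.asarray(mask), times)))
            total = None
            for head, target in heads:
                term = ag.scale(
                    ag.dice_loss(head, np.asarray(target)[None]), 1.0 / len(heads)
                )
                total = term if total is None else ag.add(total, term)
            loss = float(total.data)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {idx}: {loss}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += loss
        losses.append(epoch_loss / len(pairs))
    return model, losses


def _to_chw(image: np.ndarray, in_channels: int) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = np.stack([arr] * in_channels)
    elif arr.ndim == 3 and arr.shape[2] in (1, 3):
        arr = np.moveaxis(arr, 2, 0)
        if arr.shape[0] == 1 and in_channels == 3:
            arr = np.vstack([arr] * 3)
    else:
        raise ParameterError(f"cannot interpret image of shape {image.shape}")
    if arr.shape[0] != in_channels:
        raise ParameterError(
            f"expected {in_channels} channels, got {arr.shape[0]}"
        )
    return arr


def predict_vessels(model: UNet, frame: np.ndarray) -> np.ndarray:
    """Vessel-probability map for a frame of any size.

    The frame is resized to the model's input size, segmented, and the
    probability map is resized back to the frame's dimensions; values stay
    in [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape[:2]
    ih, iw = model.spec.input_size
    resized = resize(frame, (ih, iw), order=1, preserve_range=True, anti_aliasing=True)
    prob = model.predict(_to_chw(resized, model.spec.in_channels))
    if (h, w) != (ih, iw):
        prob = resize(prob, (h, w), order=1, preserve_range=True)
    return np.clip(prob, 0.0, 1.0)
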