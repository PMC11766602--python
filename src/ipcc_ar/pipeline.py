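"""End-to-end frame pipeline: segment, register, warp, blend.

For each intra-operative frame: predict a vessel-probability map (or treat
the frame as an already-binary vessel map in stub mode), binarize and
skeletonize it, register the pre-operative skeleton onto it with IPCC, warp
every pre-operative overlay asset by the resulting transform, and
alpha-blend the warped assets onto the frame. Frames that fail to register
reuse the last successful transform and are flagged; a stream processor
writes per-frame overlays, one JSON transform record per line, a metrics
CSV, and a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, RegistrationError
from .ipcc import IPCCConfig, RegistrationResult, ipcc_register, warp
from .metrics import registration_dice
from .preprocessing import binarize, load_image, load_mask, save_image, skeletonize
from .transform import SimilarityTransform

logger = logging.getLogger("ipcc_ar")

__all__ = [
    "OverlayAsset",
    "FrameResult",
    "PipelineConfig",
    "register_frame",
    "blend_overlay",
    "process_stream",
]

_FRAME_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class OverlayAsset:
    """A pre-operative raster to project into the surgical view.

    ``image`` lives in the pre-operative vessel map's coordinate frame;
    zero-valued pixels are treated as transparent.
    """

    image: np.ndarray
    alpha: float = 0.5
    label: str = "asset"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class FrameResult:
    index: int
    transform: SimilarityTransform | None
    failed: bool
    registration: RegistrationResult | None
    dice: float | None
    overlay: np.ndarray


@dataclass(frozen=True)
class PipelineConfig:
    ipcc: IPCCConfig = field(default_factory=IPCCConfig)
    binarize_threshold: float = 0.5
    #: initialize each frame's iteration from the previous frame's transform
    warm_start: bool = True
    #: compute the registration Dice of each frame (costs one warp + thinning)
    compute_dice: bool = True


def segment_frame(frame: np.ndarray, segmenter, threshold: float) -> np.ndarray:
    """Frame -> skeletonized binary vessel map.

    With ``segmenter=None`` (stub mode) the frame itself is taken as a
    vessel-probability map, which makes the registration path testable
    without a trained model.
    """
    if segmenter is None:
        prob = np.asarray(frame, dtype=float)
        if prob.ndim == 3:
            from .preprocessing import to_grayscale

            prob = to_grayscale(prob)
    else:
        from .segmentation import predict_vessels

        prob = predict_vessels(segmenter, frame)
    return skeletonize(binarize(prob, threshold))


def blend_overlay(
    frame: np.ndarray, warped_asset: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-pixel ``(1 - a)*frame + a*asset`` where the asset is nonzero."""
    out = np.asarray(frame, dtype=float).copy()
    asset = np.asarray(warped_asset, dtype=float)
    visible = asset > 0
    out[visible] = (1.0 - alpha) * out[visible] + alpha * asset[visible]
    return out


def register_frame(
    preop_map: np.ndarray,
    frame: np.ndarray,
    segmenter,
    assets: list[OverlayAsset],
    config: PipelineConfig | None = None,
    index: int = 0,
    previous: SimilarityTransform | None = None,
) -> FrameResult:
    """Segment a frame, register the pre-operative map onto it, overlay assets.

    ``preop_map`` must already be skeletonized. On registration failure the
    ``previous`` transform (normally the last successful frame's) is reused
    and the result is flagged; with no previous transform the frame is
    returned unmodified.
    """
    config = config or PipelineConfig()
    frame_map = segment_frame(frame, segmenter, config.binarize_threshold)
    result: RegistrationResult | None = None
    failed = False
    try:
        result = ipcc_register(
            preop_map,
            frame_map,
            config.ipcc,
            initial=previous if config.warm_start else None,
        )
        transform = result.transform
    except RegistrationError as exc:
        logger.warning("frame %d failed to register: %s", index, exc)
        failed = True
        transform = previous
    gray = np.asarray(frame, dtype=float)
    if gray.ndim == 3:
        from .preprocessing import to_grayscale

        gray = to_grayscale(gray)
    overlay = gray
    dice = None
    if transform is not None:
        h, w = frame_map.shape
        for asset in assets:
            warped = warp(
                np.asarray(asset.image, dtype=float), transform, out_size=(w, h)
            )
            overlay = blend_overlay(overlay, warped, asset.alpha)
        if config.compute_dice:
            dice = registration_dice(preop_map, frame_map, transform)
    return FrameResult(
        index=index,
        transform=transform,
        failed=failed,
        registration=result,
        dice=dice,
        overlay=overlay,
    )


def _transform_record(name: str, res: FrameResult) -> dict:
    rec: dict = {"frame": name, "failed": res.failed}
    if res.transform is not None:
        rec.update(res.transform.to_dict())
    if res.registration is not None:
        rec["iterations"] = res.registration.K
        rec["delta"] = list(res.registration.deltas)
        rec["converged"] = res.registration.converged
    if res.dice is not None:
        rec["dice"] = res.dice
    return rec


def process_stream(
    frames_dir: str | Path,
    preop_map: str | Path | np.ndarray,
    assets: list[OverlayAsset] | None = None,
    model_path: str | Path | None = None,
    out_dir: str | Path = "out",
    config: PipelineConfig | None = None,
    stub_segmenter: bool = False,
) -> dict:
    """Process every frame in a directory (lexicographic order).

    Writes ``overlays/<frame>.png``, ``transforms.jsonl`` (one JSON record
    per frame), ``metrics.csv`` and ``run.log`` under ``out_dir``; returns a
    summary dict (frame/failure/skip counts). Unreadable frames are skipped
    and logged. Without ``model_path``, ``stub_segmenter=True`` is required.
    """
    config = config or PipelineConfig()
    frames_dir = Path(frames_dir)
    out_dir = Path(out_dir)
    (out_dir / "overlays").mkdir(parents=True, exist_ok=True)
    if isinstance(preop_map, (str, Path)):
        preop = skeletonize(load_mask(preop_map))
    else:
        preop = skeletonize(np.asarray(preop_map, dtype=np.uint8))
    segmenter = None
    if model_path is not None:
        from .segmentation import load_segmenter

        segmenter = load_segmenter(model_path)
    elif not stub_segmenter:
        raise ParameterError(
            "no model_path given; pass stub_segmenter=True to treat frames "
            "as vessel maps"
        )
    assets = assets or []
    frame_paths = sorted(
        p for p in frames_dir.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not frame_paths:
        logger.warning("no frames found in %s", frames_dir)

    records: list[dict] = []
    metrics_rows: list[str] = []
    previous: SimilarityTransform | None = None
    skipped = failures = 0
    for idx, path in enumerate(frame_paths):
        try:
            frame = load_image(path)
        except Exception as exc:  # unreadable frame: skip, keep going
            logger.warning("skipping unreadable frame %s: %s", path.name, exc)
            skipped += 1
            continue
        res = register_frame(
            preop, frame, segmenter, assets, config, index=idx, previous=previous
        )
        if res.failed:
            failures += 1
        elif res.transform is not None:
            previous = res.transform
        save_image(out_dir / "overlays" / f"{path.stem}.png", res.overlay)
        records.append(_transform_record(path.name, res))
        dice = "" if res.dice is None else f"{res.dice:.6f}"
        metrics_rows.append(f"{path.name},{dice},{int(res.failed)}")

    with open(out_dir / "transforms.jsonl", "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    with open(out_dir / "metrics.csv", "w") as fh:
        fh.write("frame,dice,failed\n")
        fh.write("\n".join(metrics_rows) + ("\n" if metrics_rows else ""))
    summary = {
        "frames": len(frame_paths),
        "processed": len(records),
        "skipped": skipped,
        "failures": failures,
        "config": {
            "ipcc": vars(config.ipcc).copy(),
            "binarize_threshold": config.binarize_threshold,
            "warm_start": config.warm_start,
            "stub_segmenter": stub_segmenter,
        },
    }
    (out_dir / "run.log").write_text(json.dumps(summary, indent=2, default=str))
    return summary
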