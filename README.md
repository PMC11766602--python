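# ipcc-ar — vessel-map registration for vitreoretinal augmented reality

During vitreoretinal surgery (pars plana vitrectomy, epiretinal membrane
peeling), surgeons could benefit from seeing pre-operative diagnostic
imaging — microperimetry, retina thickness maps, OCT slices, fundus
annotations — projected directly onto the live surgical view. Doing that
requires aligning a pre-operative retinal image with every intra-operative
video frame, in real time, under illumination changes and partial occlusion
by instruments. Retinal blood vessels are the natural anchor: they are
stable, distinctive, and segmentable frame by frame.

This package implements that pipeline as a tested library plus a small CLI:

1. **Segment** — a compact deeply-supervised U-Net (three levels, three
   channels at the first convolution) predicts a vessel-probability map per
   frame; implemented in NumPy with its own reverse-mode autodiff, trainable
   on the CPU.
2. **Skeletonize** — vessel masks are thinned to unit-width centerlines so
   vessel caliber does not bias the matching.
3. **Register** — the iterative patch-wise cross-correlation (IPCC)
   algorithm estimates a similarity transform (rotation θ, uniform scale
   *s*, translation) mapping the pre-operative map *A* onto the frame map
   *B*.
4. **Overlay** — pre-operative assets are warped by the transform and
   alpha-blended onto the frame.

Everything is exercisable on synthetic retinal vessel trees with known
ground-truth motion; no external dataset is needed.

## The registration algorithm

Divide image *A* into *n* × *n* patches. Correlate each patch against every
placement in *B* using Pearson-normalized cross-correlation, so scores lie
in [−1, 1] and the acceptance threshold *t* is insensitive to illumination.
Take the two best-scoring, spatially separated patches *p₁*, *p₂* with
corners C₁A → C₁B and C₂A → C₂B. With a = C₂A − C₁A and b = C₂B − C₁B, the
similarity consistent with both correspondences is

    θ = atan2(a × b, a · b),    s = |b| / |a|

giving a rotation-scaling T_rs about the pivot (C₁Ax, C₁Ay) and a
translation T_t by C₁B − C₁A. Each iteration *k* warps *A* by the
accumulated transform, rematches, and composes
T_k = (T_t,k · T_rs,k) · T_{k−1}, stopping when the mean absolute relative
change Δ of the matrix elements falls below a tolerance or after K_max
iterations (default three — the estimate stabilizes by the third round).

## Worked example

```bash
python examples/02_register_pair.py
```

```
iteration 1: delta=0.5955 theta=-9.54 deg scale=0.9351
iteration 2: delta=0.1760 theta=-10.22 deg scale=0.9483
iteration 3: delta=0.0582 theta=-9.90 deg scale=0.9505
truth: theta=-10.00 deg scale=0.9500
mean vessel-pixel reprojection error: 0.41 px (distance between where the
estimate and the truth send each vessel pixel)
```

A synthetic vessel map was warped by a known motion (−10°, scale 0.95,
shift (15, 9) px); three IPCC iterations recover it to within half a pixel,
with Δ shrinking each round as the transform stabilizes. The other examples
cover fixture generation (`01`), overlap metrics and the per-iteration Dice
climb (`03`), overfitting the segmenter on four synthetic pairs to a
training Dice of 1.0 (`04`), and the end-to-end ten-frame overlay stream
(`05`).

The same round trip from the shell:

```bash
ipcc-ar synth --seed 3 --theta 8 --dx 10 --dy -6 --out fixture/
ipcc-ar register --fixed fixture/fixed.png --moving fixture/moving.png --out T.json
ipcc-ar overlay --frames frames/ --preop-map map.png --asset oct.png \
    --stub-segmenter --out run/
```

## Layout

```
src/ipcc_ar/
  preprocessing.py   grayscale conversion, binarization, skeletonization, I/O
  correlation.py     Pearson-normalized cross-correlation surfaces
  transform.py       similarity transforms (3x3 homogeneous)
  ipcc.py            patch grid, matching, estimation, the IPCC loop, warping
  metrics.py         Dice/Jaccard/kappa & friends, registration Dice
  synthetic.py       vessel-tree generator, fixture pairs, occlusion bands
  segmentation/      NumPy U-Net, augmentation, training, DRIVE-format reader
  pipeline.py        per-frame segment-register-overlay, stream processing
  cli.py             the `ipcc-ar` command
```

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
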