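# Methods

## Problem setting

The pipeline aligns a pre-operative retinal vessel map *A* with the vessel
map *B* segmented from each intra-operative video frame, under a similarity
motion model: rotation θ, uniform scale *s*, translation (4 degrees of
freedom, a 3×3 homogeneous matrix acting on column vectors [x, y, 1]ᵀ).
Coordinates are raster coordinates — x = column, y = row, origin top-left,
0-based — and a positive θ rotates +x toward +y (clockwise on screen with y
down). The similarity model is appropriate because the fundus is viewed
approximately fronto-parallel through the operating microscope; out-of-plane
tilt, lens distortion and retinal deformation are not modeled (see
Limitations).

## Registration (IPCC)

Inputs are *skeletonized* binary maps: morphological thinning (Zhang–Suen
8-connected, via scikit-image) reduces vessels to unit-width centerlines so
that vessel caliber — which varies with segmentation threshold and frame
quality — does not bias the correlation.

Each iteration k = 1…K:

1. Warp *A* by the accumulated transform T_{k−1} (T₀ = identity, or a
   warm-start transform from the previous frame).
2. Grid the warped map into n × n patches of ⌊w/n⌋ × ⌊h/n⌋ pixels
   (right/bottom remainder excluded; patches under 8 px per side are
   rejected as unmatchable).
3. Score each patch against every placement in *B* with Pearson-normalized
   cross-correlation (zero-mean, unit-variance normalization, scores in
   [−1, 1]). Zero-variance windows score 0; zero-variance patches are
   skipped, as are patches whose vessel density is below 1%.
4. Select the two best matches p₁, p₂ with score > t whose patch centers
   are at least one patch diagonal apart.
5. Estimate θ = atan2(a × b, a · b) and s = |b|/|a| from the inter-corner
   vectors a = C₂A − C₁A, b = C₂B − C₁B; build T_rs (rotation-scaling about
   the pivot (C₁Ax, C₁Ay), which maps to itself) and T_t (translation by
   C₁B − C₁A). This is the unique similarity mapping both correspondences
   exactly, a property the test suite asserts to 1e−9.
6. Compose T_k = (T_t,k · T_rs,k) · T_{k−1} and compute the convergence
   statistic Δ = mean over matrix elements of
   |t_{k−1,ij} − t_{k,ij}| / |t_{k,ij}|, excluding elements with
   |t_{k,ij}| < 1e−9 (the exact zeros of the homogeneous row, for which a
   relative change is undefined).
7. Stop when Δ < Δ_tol or k = K_max.

Per-iteration transforms *compose* (step 6) rather than replace each other:
the iteration refines a running estimate, re-matching with progressively
better-aligned patches, which is what makes the first iteration's coarse
match self-correcting.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| grid order n | 4 | 64 px patches at 256² carry enough curvilinear structure to be distinctive; smaller patches match ambiguously, larger ones tolerate less rotation |
| threshold t | 0.3 | Pearson scores are scale-free; 0.3 rejects noise matches while tolerating the score depression caused by rotation of thin structures |
| K_max | 3 | the transform estimate stabilizes by the third iteration; later iterations change it marginally |
| Δ_tol | 0.01 | a 1% mean relative change of the matrix is visually indistinguishable motion |
| min_separation | one patch diagonal | a short baseline between the two corners amplifies corner noise into angle error |
| match_blur_sigma | 3 px | see below |
| subpixel | on | see below |
| peak_ratio / exclusion radius | 0.9 / 10 px | see below |
| max incremental rotation / scale | 30°, [0.7, 1.4] | see below |

### Numerical choices

**Correlation normalization.** The matching score is the Pearson form of
cross-correlation (both patch and window mean-centered, normalized by both
standard deviations). A fixed threshold t then means the same thing across
frames and illumination conditions. The surface is computed with an FFT
numerator and integral-image window statistics; the test suite verifies
equality with a nested-loop Pearson scan (and with scikit-image's
`match_template`) to 1e−6. Ties in the arg-max resolve to the smallest y,
then smallest x.

**Softened matching of skeletons.** Unit-width centerlines barely overlap
under even a 1–2 px misalignment, which makes the raw correlation peak
needle-thin and brittle. Both maps are therefore Gaussian-blurred (σ = 3 px)
*for matching only*; selection, estimation and all outputs operate on the
original coordinates. The blur widens the capture basin without moving the
peak (it is a symmetric linear filter applied to both images).

**Sub-pixel peak refinement.** The integer arg-max is refined by a
three-point parabola fit per axis (offsets clamped to ±0.5 px). Refinement
is skipped when the peak is a perfect correlation, which is already exact —
this keeps self-registration exactly at the identity.

**Match distinctiveness.** A patch lying along one straight vessel
correlates almost equally well at many placements; its best placement
carries no information. A match is discarded when a secondary peak more
than 10 px from the primary scores above 0.9 × the primary (a
template-matching analogue of the feature-matching ratio test).

**Plausibility-checked pair selection.** Candidate pairs are tried in score
order — the first candidate is exactly the "two best above threshold, far
enough apart" rule — but a pair whose implied *incremental* transform
rotates more than 30° or rescales outside [0.7, 1.4] in a single iteration
is rejected and the next-best pair is tried. Real inter-frame motion is far
inside these bounds, so only estimates driven by a spurious match are
affected. Both safeguards are config-exposed and can be disabled.

**Failure semantics.** No eligible pair on the first iteration raises a
registration error (a stream caller falls back to the previous frame's
transform and flags the frame); failure on a later iteration returns the
best transform so far with `converged=False`.

**Warping.** Inverse-mapping resampling via scikit-image: bilinear for
grayscale images, nearest-neighbor for binary masks, out-of-bounds = 0. An
exact-identity transform short-circuits to a copy.

## Overlap metrics

All metrics derive from the per-pixel confusion table (foreground
positive): Dice = 2TP/(2TP+FP+FN) (identically F1), Jaccard = IoU =
TP/(TP+FP+FN), precision, recall, specificity, accuracy, and Cohen's kappa
with the standard marginal chance correction. 0/0 ratios are defined as 0
so batch evaluation over many frames never produces NaNs. Registration
Dice warps *A* by the transform and compares skeletons by default (an
option compares raw masks), over *B*'s full extent.

## Synthetic data: what it emulates, what it does not

The generator grows a vessel tree by seeded random-walk branches fanning
out radially from an optic-disc margin: per-step heading jitter
(tortuosity 0.15 rad), per-step branching probability 0.01, width tapering
by 0.8 per generation from 5 px roots, five root arcades, 256² px. These
defaults land the foreground fraction in [0.02, 0.20] (measured 0.06–0.17
across seeds), comparable to fundus vessel-map densities; out-of-band draws
regrow with adjusted depth (never beyond the requested maximum) and fail
after 10 attempts. Everything is deterministic under an integer seed.

A fixture pair warps the tree by a known similarity about the image center,
optionally removes up to half the vessel pixels under a straight
instrument-shaped band (offset solved so the removed fraction hits the
target within ±0.05 where geometrically reachable), and optionally renders
a gain/bias illumination variant in grayscale. The ground-truth pivot
differs from the algorithm's patch-corner pivots deliberately — any
similarity transform is representable about any pivot, so recovery is
tested pivot-independently via reprojection error (distances between where
the estimate and the truth send each vessel pixel).

What the fixtures do *not* emulate: segmentation noise (dropped or
hallucinated vessel segments), non-rigid retinal deformation, perspective
effects, motion blur, and the photometric content of real surgical video.
Passing the recovery suite therefore demonstrates that the algorithm
recovers similarity motion from partially occluded curvilinear structure —
not that the full system meets any clinical accuracy bar on real surgery.

The default evaluation envelope is |θ| ≤ 15°, s ∈ [0.9, 1.1], shifts up to
20 px at 256² — inter-frame retinal motion under a microscope is modest.
Typical results at these conditions (seeded, recomputed by
`scripts/acceptance.py` and the acceptance tests): median reprojection
error ≈ 0.4 px, 90th percentile ≈ 1.5 px after three iterations; with 20%
instrument occlusion the median stays ≈ 0.7 px; mean Δ at k = 4 ≈ 0.04–0.05
and the mean registration Dice climbs from ≈ 0.11 (k = 1) to ≈ 0.58 (k = 3).
The absolute Dice values on skeletons are depressed by 1-px resampling
misses and are meaningful as a trend, not as an absolute overlap.

## Segmenter

A U-Net with three encoder/decoder levels, three channels at the first
convolution doubling per level (3→6→12, bottleneck 24), two 3×3
convolutions + ReLU per block, 2×2 max-pool down, nearest-neighbor
upsampling with skip concatenation up. Deep supervision: a 1×1
convolution + sigmoid head at every decoder level; each head contributes
equally to a soft Dice loss (targets max-pooled to the head's resolution,
preserving thin vessels). Training: Adam (lr 2e−3 — 1e−3 demonstrably
underfits this very small network within 200 epochs, 5e−3 diverges), batch
size one, 200 epochs, optional paired augmentation (rotation ±15°, flips,
shear ±5°, brightness ±0.1, contrast ±10%; geometry shared between image
and mask, photometry image-only, deterministic per seed).

The network and its training loop are implemented in NumPy with a minimal
reverse-mode autodiff tape (`segmentation/_autograd.py`): im2col
convolutions, deterministic max-pool tie-breaking, closed-form Dice-loss
gradient. Input intensities are centered from [0, 1] to [−1, 1] before the
first convolution; with only three first-layer channels, zero-mean inputs
avoid the dead-activation stalls that raw offsets provoke. Training is reproducible run to run at fixed seed (pure NumPy,
no threading nondeterminism), and checkpoints reload to bit-identical
predictions. Training on real fundus data is supported through a
DRIVE-layout folder reader; reproducing published segmentation accuracy on
external datasets is out of scope here.

## Pipeline

Per frame: predict vessels (or, in stub mode, read the frame as an
already-binary map), binarize at 0.5, skeletonize, register, warp each
overlay asset, alpha-blend (`(1−α)·frame + α·asset` where the asset is
nonzero). The accumulated transform of frame f warm-starts frame f+1
(disable for per-frame independence). Failed frames reuse the last
successful transform and are flagged; unreadable files are skipped and
logged. Outputs: per-frame overlay PNGs, `transforms.jsonl`,
`metrics.csv`, and a JSON run log. Outputs are byte-deterministic for
fixed inputs and config.

## Problem sizes used in the automated checks

Oracle comparisons use 50 random surfaces up to 64²; exact-mapping checks
1000 random correspondence pairs; self-registration 20 trees; parameter
recovery 100 fixtures (4 iterations, early stop disabled, errors measured
at the third); occlusion robustness 50 fixtures at 20% removal; the
segmenter smoke test 4 pairs × 200 epochs; stream determinism two runs
over 10 frames. These sizes give stable medians/percentiles while keeping
the whole suite at around a minute of CPU.

## Known limitations

- Similarity motion only; no projective or non-rigid component.
- Two-point estimation: accuracy is bounded by the two selected corners;
  no least-squares pooling over all matches (by design — it is what makes
  the method cheap).
- Thin-structure correlation needs the matching blur; very dense or very
  sparse maps (outside roughly 1–30% foreground) degrade match quality.
- The segmenter is deliberately tiny; on real fundus data it trades
  accuracy for speed and is not expected to match large published models.
- Frames are processed independently of any inertial signal; prolonged
  full-field occlusion leads to stale transforms until vessels reappear.
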