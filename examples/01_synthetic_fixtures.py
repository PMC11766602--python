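"""Generate a synthetic retinal vessel map and a moving counterpart.

The generator grows a branching random-walk vessel tree (the kind of
curvilinear structure a fundus photograph's segmentation map contains) and
the fixture pair applies a known rotation/scale/translation to it — the
ground truth that registration is later scored against.
"""

import numpy as np

from ipcc_ar import VesselTreeParams, generate_vessel_tree, make_fixture_pair

mask = generate_vessel_tree(VesselTreeParams(seed=42))
print(f"vessel mask: {mask.shape[1]}x{mask.shape[0]} px, "
      f"foreground fraction {mask.mean():.3f}")

pair = make_fixture_pair(
    seed=42, theta=np.deg2rad(8.0), scale=1.05, d=(12.0, -6.0),
    occlusion_fraction=0.15,
)
print(f"ground-truth motion: theta={np.rad2deg(pair.truth.theta):.1f} deg, "
      f"scale={pair.truth.scale:.3f}")
print(f"moving map keeps {pair.moving.sum() / pair.fixed.sum():.2f} of the "
      "fixed map's vessel pixels (rest moved out of frame or occluded)")
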