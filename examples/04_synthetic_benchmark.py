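"""Benchmark the ensemble operators on synthetic scenes, one failure mode
at a time.

Scenes contain elongated tubular structures of up to three organ classes.
Two noise regimes isolate what each ensemble refinement repairs:

* cross-class *confusion* (a member leaks confidence onto a visually
  similar organ) scatters minority labels inside structures — region
  majority voting repairs them;
* spurious *false blobs* on one noisy member create false positives —
  down-weighting that member pushes them under the 0.5 gate.
"""

import numpy as np

from segfuse import (
    ClassWeights,
    ScenarioConfig,
    evaluate_pair,
    fuse_pixelwise,
    fuse_pixelwise_weighted,
    fuse_regionwise,
    generate_scene,
    simulate_probability_maps,
)


def mean_class_jaccard(gt, pred):
    rec = evaluate_pair(gt, pred)
    vals = [rec[f"jaccard_{c}"] for c in (1, 2, 3) if rec[f"jaccard_{c}"] is not None]
    return np.mean(vals)


n_scenes = 20

# regime 1: moderate intra-region confusion -> region majority voting wins
pixel, region = [], []
for seed in range(n_scenes):
    cfg = ScenarioConfig(presence=(1.0, 1.0, 1.0), confusion_rate=0.25, seed=seed)
    _, gt = generate_scene(cfg)
    maps = simulate_probability_maps(gt, cfg)
    pixel.append(mean_class_jaccard(gt, fuse_pixelwise(maps)))
    region.append(mean_class_jaccard(gt, fuse_regionwise(maps)))
print(f"confusion regime, mean class-level Jaccard over {n_scenes} scenes:")
print(f"  pixel-wise   {np.mean(pixel):.4f}")
print(f"  region-based {np.mean(region):.4f}   <- majority voting repairs"
      " minority labels inside each connected structure")

# regime 2: one member riddled with false blobs -> down-weighting it wins
weights = ClassWeights((1.0, 1.0, 0.6))
plain, weighted = [], []
for seed in range(n_scenes):
    cfg = ScenarioConfig(presence=(1.0, 1.0, 1.0), false_blob_rate=6.0, seed=seed)
    _, gt = generate_scene(cfg)
    maps = simulate_probability_maps(gt, cfg, member_noise={1: 0.0, 2: 0.0, 3: 1.0})
    plain.append(mean_class_jaccard(gt, fuse_pixelwise(maps)))
    weighted.append(mean_class_jaccard(gt, fuse_pixelwise_weighted(maps, weights)))
print(f"false-blob regime, mean class-level Jaccard over {n_scenes} scenes:")
print(f"  unweighted   {np.mean(plain):.4f}")
print(f"  weighted     {np.mean(weighted):.4f}   <- the noisy member's blobs"
      " fall under the 0.5 gate once down-weighted")
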