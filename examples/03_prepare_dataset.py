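"""Data preparation: fill boundary annotations into masks, binarize per
class, cut constrained crop augmentations, and split frames by video."""

import numpy as np

from segfuse import (
    DatasetIndex,
    binarize_mask,
    group_split,
    merge_class_masks,
    rasterize_boundary,
    slice_crops,
)

# 1. Annotated boundaries -> filled per-class masks -> one ground-truth map.
artery = rasterize_boundary([(100, 80), (700, 120), (680, 220), (120, 180)], 1340, 648)
ureter = rasterize_boundary([(300, 400), (900, 380), (920, 470), (320, 500)], 1340, 648)
gt, overlap = merge_class_masks({1: artery, 2: ureter})
print(f"ground truth: {np.count_nonzero(gt.labels)} labeled px, overlap {overlap}")
print("artery binary target px:", binarize_mask(gt, 1).sum())

# 2. Crop augmentation: 24 sub-images of 512x512, each keeping at least a
#    third of the frame's labeled pixels.
image = np.zeros((648, 1340, 3), np.uint8)
crops = slice_crops(image, gt, n=24, side=512, min_fraction=1 / 3, seed=4)
fractions = [w.labeled_fraction for *_, w in crops]
print(f"{len(crops)} crops, labeled fraction {min(fractions):.3f}-{max(fractions):.3f}")

# 3. Video-grouped split: frames of one video are near-duplicates, so a
#    video never spans two folds.
records = {f"v{v:02d}_f{f}": f"v{v:02d}" for v in range(10) for f in range(v % 4 + 2)}
split = group_split(DatasetIndex(records), k=5, test_videos=("v00",), seed=0)
for fold in sorted(set(split.assignments.values())):
    vids = [v for v, a in split.assignments.items() if a == fold]
    n = sum(1 for img, v in records.items() if v in vids)
    print(f"{fold}: {len(vids)} videos, {n} frames")
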