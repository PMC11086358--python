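# Methods

## Fusion model

The package merges `m` one-vs-all binary segmentation outputs
`P_i(x, y) ∈ [0, 1]` into one label map `P(x, y) ∈ {0} ∪ {class ids}`.
Default classes are 1 = uterine artery, 2 = ureter, 3 = nerve; 0 is always
background and never competes in any argmax — it arises solely from the
confidence gate.

**Gate semantics.** A pixel is background iff *every* (weighted) confidence
is strictly below the threshold (default 0.5); a confidence of exactly 0.5
counts as positive. The threshold is configurable but weighted operators
keep it fixed, which is why weights above 1 are rejected: a super-unit
weight would silently lower the effective per-class threshold.

**Ties.** Argmax ties (pixel-wise) and majority ties (region-based) break
toward the lowest class id. Any deterministic rule would do; this one is the
natural order of the class list and makes outputs reproducible bit-for-bit.

**Regions.** Components are extracted from the *class-agnostic* foreground
(the binarized union of all classes), not per class — a structure whose
interior flickers between two classes must form one component for majority
voting to repair it. Connectivity defaults to 8 (diagonally continuous
tubular structures stay whole) and is exposed as `{4, 8}`. In the weighted
region-based operator the components come from the *weighted* pixel-wise
map's foreground: a pixel gated out by weighting is excluded from every
region and stays background.

**Weights.** Member weights are treated as opaque values in `(0, 1]`
supplied by the user; the intended provenance is each binary member's
held-out accuracy (e.g. its per-class Dice), but nothing in the library
depends on which accuracy metric is chosen, and no normalization is applied.

## Metrics

Image-level scores formalize both maps as sets of `(pixel, label)` pairs
over all `N = W·H` pixels, background included: with `a` agreeing pixels,
`Dice = a/N` (the agreement rate) and `Jaccard = a/(2N − a)`, so
`J = D/(2 − D)` holds exactly per image. Counting background agreement is
deliberate: organ supports are small, and a background-free global score
would be dominated by noise in tiny foregrounds.

Class-level scores are the standard binary IoU and Dice of the two class
supports, linked by `D_c = 2J_c/(1 + J_c)`. A class absent from both maps is
**undefined** (not 0, not 1) and excluded from that class's dataset mean;
scoring 0/0 as 1 would inflate rare-class results, and every report carries
the defined-image count per metric so the averaging population is explicit.
Dataset aggregation is per-image-then-unweighted-mean; a pooled-pixel
variant exists (`evaluate_dataset_pooled`) but is not the default.

## Data preparation

**Rasterization.** Boundary polygons are filled with an even-odd
crossing-number test at integer pixel centers, with pixels exactly on a
polygon edge counted as foreground (an annotated boundary belongs to the
organ). This is implemented directly — the exact fill rule and boundary
convention are part of the operation's contract — and is cross-checked in
tests against an independent geometric predicate (shapely) on simple
polygons. Merging per-class masks resolves overlaps toward the lowest class
id and reports the overlap pixel count.

**Crop augmentation.** `slice_crops` returns exactly `n` (default 24)
square windows (default 512×512) per frame, each containing at least
`min_fraction` (default 1/3) **of the source frame's total labeled pixel
count** — not "1/3 of the crop labeled", which small organs could never
satisfy in a 512×512 window. Windows are drawn by seeded rejection sampling
of the top-left corner (window sums come from a summed-area table, so each
test is O(1)); after `max_attempts` (default 1000) rejections a draw falls
back deterministically to the window centered on the foreground centroid,
clamped into bounds. If even a coarse scan of placements cannot reach
`min_fraction` the call fails, reporting the best achievable fraction.
Duplicate windows are allowed (a frame exactly 512×512 yields 24 copies of
its only valid crop).

**Grouped splitting.** Frames of one video are near-duplicates, so
cross-validation folds are assigned at video level: held-out test videos are
marked `test`, the remaining video ids are shuffled with the seed (breaking
ties among equal-sized videos), then placed largest-first into the currently
smallest fold by image count. Fold sizes therefore differ by at most the
largest single video.

## Synthetic data

The generator emulates the study's data regime, not its appearance: frames
contain 0–3 elongated tubular structures (quadratic Bézier paths dilated to
a random width of 8–22 px) on a textured background, with per-class presence
probabilities defaulting to (0.8, 0.45, 0.25) to mirror the strong
artery > ureter > nerve frequency imbalance of real annotations. Structures
of different classes are kept 8-disconnected (a 1-px tissue gap), as
distinct organs are in real scenes; without that separation, touching
organs would merge into one component and majority relabeling could not
recover the ground truth even from perfect inputs. "Videos" share one
geometry seed across frames, varying only the noise realization — exactly
the inter-frame correlation that motivates grouped splitting.

Member outputs are corruptions of the per-class binarized ground truth,
each failure mode independently switchable:

| parameter | meaning | default |
|---|---|---|
| `blur_radius` | Gaussian σ (px): soft structure edges | 0 |
| `speckle_rate` | fraction of pixels with confidence resampled uniformly | 0 |
| `confusion_rate` | fraction of another class's support leaking confidence ≥ 0.55 into this map, with the true support jittered so leaks can win | 0 |
| `false_blob_rate` | expected count of spurious high-confidence background blobs (Poisson), scalable per member | 0 |
| `calibration_sharpness` | slope of a logistic squash around 0.5, normalized to fix 0, 0.5 and 1 exactly | 8 |

With every rate zero the maps equal the binarized ground truth and all four
operators return it bit-for-bit — the noiseless-recovery check. The squash's
endpoint normalization is what makes that exactness possible at any finite
sharpness.

What the synthetic regime does *not* model: photorealistic tissue, specular
highlights, camera motion, occlusion by instruments, or correlated
(non-pixel-independent) confusion. Passing tests therefore demonstrate the
correctness and the *direction* of the ensemble effects — region voting
repairs intra-region confusion, down-weighting a blob-ridden member removes
its false positives — not the magnitudes attainable on surgical images with
trained networks.

## Numerical and I/O choices

Probability maps are stored as 16-bit grayscale PNGs (`v / 65535`), bounding
round-trip error by one quantization step with exact endpoints; label maps
as 8-bit PNGs with literal values. Coordinates are (x, y) = (column, row),
0-based. Pipeline runs write a JSON manifest (config echo, versions, stage
timings, warnings) sufficient to reproduce the run; existing outputs are
never overwritten without an explicit force flag.

Test and acceptance problem sizes — 64×64 random map sets for brute-force
agreement, 256×192 scenes, 20–50 seeds per Monte-Carlo comparison — were
chosen as the smallest sizes at which every behavior under test (multiple
components per image, all three classes co-occurring, stable sign-test
majorities) occurs reliably.

## Known limitations

* Majority relabeling assumes each connected component belongs to one
  organ; genuinely touching organs (absent from the synthetic regime by
  construction) would be flattened to a single class.
* The even-odd fill differs from shapely-style interior tests on
  self-intersecting polygons; annotation polygons are assumed simple.
* Weighted fusion can *hurt* when the down-weighted member is also the only
  confident source for its own class (its true detections fall under the
  gate); weights should come from held-out member accuracy, not be tuned on
  test data.
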