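"""Jaccard and Dice evaluation of multi-class label maps.

Global (image-level) metrics formalize the ground truth ``gt`` and prediction
``P`` as sets of ``(pixel, label)`` pairs over all W*H pixels, background
included.  With ``a`` the number of pixels whose labels agree and ``N = W*H``:

    Jaccard(gt, P) = a / (2N - a)          Dice(gt, P) = a / N

so the global Dice is the pixel agreement rate and the two are linked by
``J = D / (2 - D)`` exactly.  Class-level metrics restrict both maps to one
organ's binary support and use the usual binary IoU / Dice, linked by
``D_c = 2 J_c / (1 + J_c)``.  A class absent from both maps yields an
*undefined* value (``None``) rather than an arbitrary 0 or 1, and undefined
values are excluded from dataset means.
"""

from __future__ import annotations

import numpy as np

from .types import LabelMap, MetricReport

__all__ = [
    "jaccard_global",
    "dice_global",
    "jaccard_class",
    "dice_class",
    "evaluate_pair",
    "evaluate_dataset",
]


def _arrays(gt: LabelMap, pred: LabelMap) -> tuple[np.ndarray, np.ndarray]:
    a, b = gt.labels, pred.labels
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: gt {a.shape} vs pred {b.shape}")
    return a, b


def jaccard_global(gt: LabelMap, pred: LabelMap) -> float:
    """Image-level Jaccard over (pixel, label) pairs, background included."""
    a, b = _arrays(gt, pred)
    agree = int(np.count_nonzero(a == b))
    n = a.size
    return agree / (2 * n - agree)


def dice_global(gt: LabelMap, pred: LabelMap) -> float:
    """Image-level Dice over (pixel, label) pairs: the pixel agreement rate."""
    a, b = _arrays(gt, pred)
    return int(np.count_nonzero(a == b)) / a.size


def _class_supports(gt: LabelMap, pred: LabelMap, c: int) -> tuple[int, int, int]:
    if c not in gt.class_ids and c not in pred.class_ids:
        raise ValueError(f"unknown class id {c}")
    a, b = _arrays(gt, pred)
    gtc = a == c
    pc = b == c
    inter = int(np.count_nonzero(gtc & pc))
    return inter, int(np.count_nonzero(gtc)), int(np.count_nonzero(pc))


def jaccard_class(gt: LabelMap, pred: LabelMap, c: int) -> float | None:
    """Binary IoU of class ``c``; ``None`` when absent from both maps."""
    inter, n_gt, n_pred = _class_supports(gt, pred, c)
    union = n_gt + n_pred - inter
    if union == 0:
        return None
    return inter / union


def dice_class(gt: LabelMap, pred: LabelMap, c: int) -> float | None:
    """Binary Dice of class ``c``; ``None`` when absent from both maps."""
    inter, n_gt, n_pred = _class_supports(gt, pred, c)
    if n_gt + n_pred == 0:
        return None
    return 2 * inter / (n_gt + n_pred)


def evaluate_pair(
    gt: LabelMap, pred: LabelMap, class_ids: tuple[int, ...] | None = None
) -> dict:
    """All eight metrics for one (gt, prediction) pair."""
    ids = tuple(class_ids) if class_ids is not None else gt.class_ids
    rec: dict = {
        "jaccard": jaccard_global(gt, pred),
        "dice": dice_global(gt, pred),
    }
    for c in ids:
        rec[f"jaccard_{c}"] = jaccard_class(gt, pred, c)
        rec[f"dice_{c}"] = dice_class(gt, pred, c)
    return rec


def evaluate_dataset(
    pairs: list[tuple[LabelMap, LabelMap]],
    class_ids: tuple[int, ...] | None = None,
    image_ids: list[str] | None = None,
) -> MetricReport:
    """Per-image metrics and their unweighted means over the dataset.

    Aggregation is per-image-then-mean; a metric undefined on an image simply
    does not contribute to its mean, and ``defined_counts`` records how many
    images did.
    """
    if not pairs:
        raise ValueError("evaluate_dataset requires at least one (gt, pred) pair")
    if image_ids is None:
        image_ids = [f"image_{i:04d}" for i in range(len(pairs))]
    ids = tuple(class_ids) if class_ids is not None else pairs[0][0].class_ids

    report = MetricReport(class_ids=ids)
    for img_id, (gt, pred) in zip(image_ids, pairs):
        try:
            rec = evaluate_pair(gt, pred, ids)
        except ValueError as exc:
            raise ValueError(f"{img_id}: {exc}") from exc
        report.per_image.append({"image_id": img_id, **rec})

    keys = [k for k in report.per_image[0] if k != "image_id"]
    for key in keys:
        defined = [r[key] for r in report.per_image if r[key] is not None]
        report.defined_counts[key] = len(defined)
        report.aggregate[key] = float(np.mean(defined)) if defined else None
    return report


def evaluate_dataset_pooled(
    pairs: list[tuple[LabelMap, LabelMap]],
    class_ids: tuple[int, ...] | None = None,
) -> dict:
    """Pooled-pixel alternative: metrics over all pixels of all images at once.

    Not the default aggregation; provided for comparison with the per-image
    mean.
    """
    if not pairs:
        raise ValueError("at least one pair required")
    ids = tuple(class_ids) if class_ids is not None else pairs[0][0].class_ids
    gt_all = np.concatenate([g.labels.ravel() for g, _ in pairs])
    pr_all = np.concatenate([p.labels.ravel() for _, p in pairs])
    gt = LabelMap(gt_all[None, :], ids)
    pr = LabelMap(pr_all[None, :], ids)
    return evaluate_pair(gt, pr, ids)
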