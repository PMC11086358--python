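"""Data preparation: boundary rasterization, mask merging, per-class
binarization, constrained crop augmentation and video-grouped splitting.

These procedures turn expert boundary annotations into multi-class ground
truth, expand a small dataset by label-constrained random cropping, and
partition frames into cross-validation folds without splitting any source
video — frames of one video are near-duplicates, so video-level grouping
prevents train/validation leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LabelMap


# ---------------------------------------------------------------------------
# boundary annotations -> masks

@dataclass(frozen=True)
class CropWindow:
    """A square crop: top-left (x, y), side length, and the fraction of the
    source image's labeled pixels the window retains."""

    x: int
    y: int
    side: int
    labeled_fraction: float


def rasterize_boundary(polygon, width: int, height: int) -> np.ndarray:
    """Fill a closed boundary polygon into a binary mask.

    Pixel centers sit at integer coordinates; a pixel is foreground when its
    center lies strictly inside the polygon under the even-odd rule, or
    exactly on a polygon edge (annotated boundaries belong to the organ).
    Vertex order and orientation do not matter.

    ``polygon`` is a sequence of (x, y) vertices; the closing edge from the
    last vertex back to the first is implicit.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError(f"polygon needs >= 3 (x, y) vertices, got shape {poly.shape}")
    if np.any(poly[:, 0] < 0) or np.any(poly[:, 0] > width - 1) or \
       np.any(poly[:, 1] < 0) or np.any(poly[:, 1] > height - 1):
        raise ValueError("polygon vertices outside image bounds")
    rel = poly[1:] - poly[0]
    nz = rel[np.any(rel != 0, axis=1)]
    if nz.size == 0 or np.allclose(
        rel[:, 0] * nz[0, 1] - rel[:, 1] * nz[0, 0], 0.0
    ):
        raise ValueError("degenerate polygon: zero area (collinear vertices)")

    x0, x1 = int(np.floor(poly[:, 0].min())), int(np.ceil(poly[:, 0].max()))
    y0, y1 = int(np.floor(poly[:, 1].min())), int(np.ceil(poly[:, 1].max()))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)

    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = poly.shape[0]
    for i in range(n):
        ax, ay = poly[i]
        bx, by = poly[(i + 1) % n]
        # even-odd crossing: count edges crossing the upward ray from the point
        cross = ((ay > py) != (by > py)) & (
            px < (bx - ax) * (py - ay) / (by - ay + ((by - ay) == 0)) + ax
        )
        inside ^= cross
        # point-on-segment: collinear and within the bounding box
        collinear = np.isclose((bx - ax) * (py - ay) - (by - ay) * (px - ax), 0.0)
        within = (
            (px >= min(ax, bx) - 1e-9) & (px <= max(ax, bx) + 1e-9)
            & (py >= min(ay, by) - 1e-9) & (py <= max(ay, by) + 1e-9)
        )
        on_edge |= collinear & within

    if not np.any(inside | on_edge):
        raise ValueError("degenerate polygon: covers no pixel center")

    mask = np.zeros((height, width), dtype=np.uint8)
    keep = inside | on_edge
    mask[py[keep].astype(int), px[keep].astype(int)] = 1
    return mask


def merge_class_masks(
    masks: dict[int, np.ndarray],
) -> tuple[LabelMap, int]:
    """Merge per-class binary masks into one ground-truth label map.

    Background where every mask is 0; elsewhere the covering class's id.
    Where annotations overlap, the lowest class id takes precedence
    (deterministic) and the number of overlapping pixels is returned so the
    caller can log it.
    """
    ids = tuple(sorted(masks))
    shapes = {c: np.asarray(masks[c]).shape for c in ids}
    if len(set(shapes.values())) > 1:
        detail = ", ".join(f"class {c}: {s}" for c, s in shapes.items())
        raise ValueError(f"mask dimension mismatch ({detail})")
    stack = np.stack([np.asarray(masks[c]) != 0 for c in ids])
    coverage = stack.sum(axis=0)
    overlap = int(np.count_nonzero(coverage > 1))
    labels = np.zeros(stack.shape[1:], dtype=np.int64)
    for cid, m in zip(reversed(ids), reversed(stack)):  # lowest id wins last
        labels[m] = cid
    return LabelMap(labels, ids), overlap


def binarize_mask(labels: LabelMap, c: int) -> np.ndarray:
    """One-vs-all binary target for class ``c``: 1 where the label equals
    ``c``, 0 elsewhere."""
    if c not in labels.class_ids:
        raise ValueError(f"unknown class id {c}; declared: {labels.class_ids}")
    return (labels.labels == c).astype(np.uint8)


# ---------------------------------------------------------------------------
# crop augmentation

def slice_crops(
    image: np.ndarray,
    labels: LabelMap,
    n: int = 24,
    side: int = 512,
    min_fraction: float = 1.0 / 3.0,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1000,
) -> list[tuple[np.ndarray, LabelMap, CropWindow]]:
    """Cut ``n`` square sub-images that each retain enough of the labels.

    Windows of ``side`` x ``side`` pixels are drawn by seeded rejection
    sampling (uniform top-left corner, fully in bounds); a window is accepted
    when it contains at least ``min_fraction`` of the source image's total
    labeled (non-background) pixel count.  If ``max_attempts`` draws are all
    rejected, the draw falls back deterministically to the window centered on
    the foreground centroid, clamped into bounds.  Duplicate windows are
    permitted; identical seeds reproduce identical windows.
    """
    image = np.asarray(image)
    H, W = labels.height, labels.width
    if image.shape[:2] != (H, W):
        raise ValueError(f"image {image.shape[:2]} vs labels {(H, W)}")
    if H < side or W < side:
        raise ValueError(f"image {W}x{H} smaller than crop side {side}")
    total = int(np.count_nonzero(labels.labels))
    if total == 0:
        raise ValueError("label map is entirely background; constraint unsatisfiable")

    fg = labels.foreground.astype(np.int64)
    # summed-area table: labeled-pixel count of any window in O(1)
    sat = np.zeros((H + 1, W + 1), dtype=np.int64)
    sat[1:, 1:] = fg.cumsum(0).cumsum(1)

    def window_count(y: int, x: int) -> int:
        return int(
            sat[y + side, x + side] - sat[y, x + side] - sat[y + side, x] + sat[y, x]
        )

    rows, cols = np.nonzero(fg)
    cy, cx = float(rows.mean()), float(cols.mean())
    fb_y = int(np.clip(round(cy - side / 2), 0, H - side))
    fb_x = int(np.clip(round(cx - side / 2), 0, W - side))
    fallback = (fb_y, fb_x)
    if window_count(*fallback) < min_fraction * total:
        best = max(
            window_count(y, x)
            for y in range(0, H - side + 1, max(1, (H - side) // 32 or 1))
            for x in range(0, W - side + 1, max(1, (W - side) // 32 or 1))
        )
        if best < min_fraction * total:
            raise ValueError(
                "min_fraction unsatisfiable by any sampled window; best achievable "
                f"fraction ~{best / total:.3f} < {min_fraction:.3f}"
            )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[tuple[np.ndarray, LabelMap, CropWindow]] = []
    for _ in range(n):
        placed = None
        for _ in range(max_attempts):
            y = int(rng.integers(0, H - side + 1))
            x = int(rng.integers(0, W - side + 1))
            if window_count(y, x) >= min_fraction * total:
                placed = (y, x)
                break
        if placed is None:
            placed = fallback
            if window_count(*placed) < min_fraction * total:
                raise ValueError(
                    "centroid fallback window holds only "
                    f"{window_count(*placed) / total:.3f} of the labeled pixels "
                    f"(< {min_fraction:.3f})"
                )
        y, x = placed
        win = CropWindow(x, y, side, window_count(y, x) / total)
        crop_img = image[y : y + side, x : x + side].copy()
        crop_lab = LabelMap(labels.labels[y : y + side, x : x + side].copy(), labels.class_ids)
        out.append((crop_img, crop_lab, win))
    return out


# ---------------------------------------------------------------------------
# video-grouped splitting

@dataclass
class DatasetIndex:
    """Dataset catalogue: one record per frame, plus split assignments.

    ``records`` maps image id -> video id.  ``assignments`` maps video id to
    either ``"test"`` or a fold name ``"fold_<k>"``; all frames of one video
    share its video's assignment.
    """

    records: dict[str, str]
    assignments: dict[str, str] | None = None

    def videos(self) -> dict[str, list[str]]:
        by_video: dict[str, list[str]] = {}
        for img, vid in self.records.items():
            by_video.setdefault(vid, []).append(img)
        return by_video

    def split_of(self, image_id: str) -> str | None:
        if self.assignments is None:
            return None
        return self.assignments[self.records[image_id]]


def group_split(
    index: DatasetIndex,
    k: int = 5,
    test_videos: tuple[str, ...] = (),
    seed: int = 0,
) -> DatasetIndex:
    """Assign whole videos to ``k`` folds (plus an optional held-out test set).

    Test videos are marked ``"test"`` and excluded from the folds.  Remaining
    videos are shuffled with the seed, then placed largest-first into the
    currently smallest fold (by image count), so fold sizes stay balanced and
    no video ever spans two assignments.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    by_video = index.videos()
    unknown = set(test_videos) - set(by_video)
    if unknown:
        raise ValueError(f"unknown test videos: {sorted(unknown)}")
    pool = [v for v in by_video if v not in set(test_videos)]
    if len(pool) < k:
        raise ValueError(f"{len(pool)} non-test videos cannot fill {k} folds")

    rng = np.random.default_rng(seed)
    pool = [pool[i] for i in rng.permutation(len(pool))]
    pool.sort(key=lambda v: -len(by_video[v]))  # stable: shuffle breaks ties

    assignments: dict[str, str] = {v: "test" for v in test_videos}
    fold_sizes = [0] * k
    for vid in pool:
        target = int(np.argmin(fold_sizes))
        assignments[vid] = f"fold_{target}"
        fold_sizes[target] += len(by_video[vid])
    return DatasetIndex(dict(index.records), assignments)
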