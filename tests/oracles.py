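"""Independent brute-force reference implementations used only by tests.

These evaluate the fusion and metric definitions literally — explicit loops
over pixels, flood-fill component search, set-based metric counting — with no
code shared with the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from collections import Counter, deque

import numpy as np


def pixelwise_oracle(maps, class_ids, weights=None, threshold=0.5):
    """Per-pixel gate + argmax, evaluated one pixel at a time."""
    C, H, W = np.asarray(maps).shape
    if weights is None:
        weights = [1.0] * C
    out = np.zeros((H, W), dtype=np.int64)
    for y in range(H):
        for x in range(W):
            scores = [weights[i] * maps[i][y][x] for i in range(C)]
            if all(s < threshold for s in scores):
                continue
            best, best_score = None, -1.0
            for i in range(C):  # first maximum -> lowest class id
                if scores[i] > best_score:
                    best, best_score = class_ids[i], scores[i]
            out[y, x] = best
    return out


def flood_fill_components(labels, connectivity=8):
    """List of components (each a list of (y, x)) of the nonzero support."""
    H, W = labels.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    seen = np.zeros((H, W), dtype=bool)
    components = []
    for y in range(H):
        for x in range(W):
            if labels[y, x] == 0 or seen[y, x]:
                continue
            queue = deque([(y, x)])
            seen[y, x] = True
            comp = []
            while queue:
                cy, cx = queue.popleft()
                comp.append((cy, cx))
                for dy, dx in nbrs:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < H and 0 <= nx < W and not seen[ny, nx] and labels[ny, nx] != 0:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            components.append(comp)
    return components


def regionwise_oracle(maps, class_ids, weights=None, threshold=0.5, connectivity=8):
    """Pixel-wise oracle, flood-fill components, per-region histogram argmax."""
    pw = pixelwise_oracle(maps, class_ids, weights, threshold)
    out = pw.copy()
    for comp in flood_fill_components(pw, connectivity):
        counts = Counter(pw[y, x] for y, x in comp)
        winner = min(
            counts, key=lambda c: (-counts[c], c)
        )  # most frequent, ties -> lowest id
        for y, x in comp:
            out[y, x] = winner
    return out


def jaccard_global_oracle(gt, pred):
    """Set-of-(pixel,label)-pairs Jaccard, built from explicit pair sets."""
    a = {((y, x), int(gt[y, x])) for y in range(gt.shape[0]) for x in range(gt.shape[1])}
    b = {((y, x), int(pred[y, x])) for y in range(gt.shape[0]) for x in range(gt.shape[1])}
    return len(a & b) / len(a | b)


def dice_global_oracle(gt, pred):
    a = {((y, x), int(gt[y, x])) for y in range(gt.shape[0]) for x in range(gt.shape[1])}
    b = {((y, x), int(pred[y, x])) for y in range(gt.shape[0]) for x in range(gt.shape[1])}
    return 2 * len(a & b) / (len(a) + len(b))


def class_metric_oracle(gt, pred, c):
    """(jaccard_c, dice_c) from explicit pixel sets; (None, None) if 0/0."""
    a = {(y, x) for y in range(gt.shape[0]) for x in range(gt.shape[1]) if gt[y, x] == c}
    b = {(y, x) for y in range(gt.shape[0]) for x in range(gt.shape[1]) if pred[y, x] == c}
    if not a and not b:
        return None, None
    inter = len(a & b)
    return inter / len(a | b), 2 * inter / (len(a) + len(b))
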