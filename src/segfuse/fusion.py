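"""Ensemble fusion of one-vs-all probability maps into a multi-class label map.

Four operators are provided.  The pixel-wise ensemble assigns each pixel the
class of maximum confidence, gated at 0.5: a pixel is background iff every
class confidence is strictly below the gate.  The weighted variant scales each
class's confidences by its member accuracy before both the gate and the
argmax.  The region-based variants take the (weighted) pixel-wise result,
extract connected components of its class-agnostic foreground, and relabel
every component with its most frequent class, removing inconsistent labels
inside a single contiguous structure.

Ties — in the argmax and in the region majority — are broken toward the
lowest class id, deterministically.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import ClassWeights, LabelMap, ProbabilityMapSet, RegionSet

#: Confidence gate: a pixel is foreground iff some (weighted) confidence
#: reaches this value.  Exactly 0.5 counts as positive.
GATE = 0.5

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def fuse_pixelwise(maps: ProbabilityMapSet, *, threshold: float = GATE) -> LabelMap:
    """Maximum-confidence fusion with a background gate.

    Each pixel gets the class id of the highest-confidence map, unless all
    confidences are strictly below ``threshold``, in which case it is
    background.  Ties go to the lowest class id.
    """
    return _fuse_pixels(maps, weights=None, threshold=threshold)


def fuse_pixelwise_weighted(
    maps: ProbabilityMapSet, weights: ClassWeights, *, threshold: float = GATE
) -> LabelMap:
    """As :func:`fuse_pixelwise` with confidences scaled by member accuracies.

    Every confidence ``P_i`` is replaced by ``w_i * P_i`` before both the gate
    and the argmax; with all weights equal to 1 the result is bit-identical to
    the unweighted operator.
    """
    return _fuse_pixels(maps, weights=weights, threshold=threshold)


def _fuse_pixels(
    maps: ProbabilityMapSet, weights: ClassWeights | None, threshold: float
) -> LabelMap:
    stack = maps.maps
    if weights is not None:
        stack = stack * weights.for_maps(maps)[:, None, None]
    # argmax returns the first maximal index; class_ids are ascending, so
    # ties land on the lowest class id.
    winner = np.argmax(stack, axis=0)
    peak = np.max(stack, axis=0)
    labels = np.asarray(maps.class_ids, dtype=np.int64)[winner]
    labels[peak < threshold] = 0
    return LabelMap(labels, maps.class_ids)


def extract_foreground_regions(labels: LabelMap, *, connectivity: int = 8) -> RegionSet:
    """Connected components of the class-agnostic foreground.

    The label map is binarized (any organ class vs background) and maximal
    connected components are extracted under the requested connectivity
    (8 by default, so diagonally continuous tubular structures stay whole).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    comp, n = ndimage.label(labels.foreground, structure=_STRUCTURES[connectivity])
    return RegionSet(comp, int(n), connectivity)


def region_majority_label(region: np.ndarray, labels: LabelMap) -> int:
    """Most frequent class id among the pixels of one region.

    ``region`` is an (N, 2) array of (row, col) coordinates, all foreground
    in ``labels``.  Ties are broken toward the lowest class id.
    """
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("region is empty")
    values = labels.labels[region[:, 0], region[:, 1]]
    if np.any(values == 0):
        raise ValueError("region contains background pixels")
    counts = np.bincount(values)
    return int(np.argmax(counts))  # first maximum = lowest class id


def fuse_regionwise(
    maps: ProbabilityMapSet, *, threshold: float = GATE, connectivity: int = 8
) -> LabelMap:
    """Pixel-wise fusion followed by connected-component majority relabeling.

    The foreground support is exactly that of the pixel-wise result; only
    class labels within each component change, so every component of the
    output carries a single class.
    """
    pixelwise = fuse_pixelwise(maps, threshold=threshold)
    return relabel_regions(pixelwise, connectivity=connectivity)


def fuse_regionwise_weighted(
    maps: ProbabilityMapSet,
    weights: ClassWeights,
    *,
    threshold: float = GATE,
    connectivity: int = 8,
) -> LabelMap:
    """Weighted pixel-wise fusion followed by majority relabeling.

    Regions are extracted from the weighted pixel-wise map's foreground (the
    gate is applied to weighted confidences before components are formed).
    With all weights 1 this equals :func:`fuse_regionwise` bit-exactly.
    """
    pixelwise = fuse_pixelwise_weighted(maps, weights, threshold=threshold)
    return relabel_regions(pixelwise, connectivity=connectivity)


def relabel_regions(labels: LabelMap, *, connectivity: int = 8) -> LabelMap:
    """Rewrite every connected foreground component with its majority class."""
    regions = extract_foreground_regions(labels, connectivity=connectivity)
    if regions.n_regions == 0:
        return labels
    comp = regions.component_labels
    n_max = max(labels.class_ids)
    out = labels.labels.copy()
    # joint histogram: rows = component id, cols = class label
    hist = np.zeros((regions.n_regions + 1, n_max + 1), dtype=np.int64)
    np.add.at(hist, (comp.ravel(), labels.labels.ravel()), 1)
    hist[:, 0] = -1  # background never competes in the majority
    majority = np.argmax(hist, axis=1)  # ties -> lowest class id
    fg = comp > 0
    out[fg] = majority[comp[fg]]
    return LabelMap(out, labels.class_ids)
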