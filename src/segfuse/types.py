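"""Domain containers shared across the package.

Arrays follow the image convention ``(H, W)`` with 0-based indices; a pixel
coordinate ``(x, y)`` means column ``x``, row ``y``.  Label value 0 is always
background; organ classes are positive integers (default ``1`` uterine artery,
``2`` ureter, ``3`` nerve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CLASS_IDS = (1, 2, 3)


def _validate_class_ids(class_ids: tuple[int, ...]) -> tuple[int, ...]:
    ids = tuple(int(c) for c in class_ids)
    if len(ids) == 0:
        raise ValueError("at least one class id is required")
    if any(c <= 0 for c in ids):
        raise ValueError(f"class ids must be positive (0 is background): {ids}")
    if len(set(ids)) != len(ids):
        raise ValueError(f"class ids must be distinct: {ids}")
    if list(ids) != sorted(ids):
        raise ValueError(f"class ids must be sorted ascending: {ids}")
    return ids


@dataclass(frozen=True)
class ProbabilityMapSet:
    """Per-class confidence grids produced by one-vs-all binary models.

    ``maps`` is a ``(C, H, W)`` float array; ``maps[i]`` holds the confidence
    of class ``class_ids[i]`` at every pixel, each value in ``[0, 1]``.
    """

    maps: np.ndarray
    class_ids: tuple[int, ...] = DEFAULT_CLASS_IDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_ids", _validate_class_ids(self.class_ids))
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 3:
            raise ValueError(f"maps must be a (C, H, W) array, got shape {maps.shape}")
        if maps.shape[0] != len(self.class_ids):
            raise ValueError(
                f"{maps.shape[0]} maps for {len(self.class_ids)} class ids"
            )
        for cid, grid in zip(self.class_ids, maps):
            lo, hi = float(np.min(grid)), float(np.max(grid))
            if lo < 0.0 or hi > 1.0:
                raise ValueError(
                    f"confidences for class {cid} outside [0, 1]: "
                    f"range [{lo:.6g}, {hi:.6g}]"
                )
        object.__setattr__(self, "maps", maps)

    @classmethod
    def from_dict(cls, per_class: dict[int, np.ndarray]) -> "ProbabilityMapSet":
        ids = tuple(sorted(per_class))
        shapes = {c: np.asarray(per_class[c]).shape for c in ids}
        if len(set(shapes.values())) > 1:
            detail = ", ".join(f"class {c}: {s}" for c, s in shapes.items())
            raise ValueError(f"probability maps disagree in shape ({detail})")
        return cls(np.stack([np.asarray(per_class[c], float) for c in ids]), ids)

    @property
    def height(self) -> int:
        return self.maps.shape[1]

    @property
    def width(self) -> int:
        return self.maps.shape[2]


@dataclass(frozen=True)
class ClassWeights:
    """Member accuracies applied to probability maps, one per class, in (0, 1].

    Weights above 1 are rejected: with the fixed 0.5 confidence gate a
    super-unit weight would silently lower the effective threshold.
    """

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in np.atleast_1d(np.asarray(self.weights, float)))
        for v in w:
            if not (0.0 < v <= 1.0):
                raise ValueError(f"weights must lie in (0, 1], got {v}")
        object.__setattr__(self, "weights", w)

    def for_maps(self, maps: ProbabilityMapSet) -> np.ndarray:
        if len(self.weights) != len(maps.class_ids):
            raise ValueError(
                f"{len(self.weights)} weights for {len(maps.class_ids)} classes"
            )
        return np.asarray(self.weights, float)


@dataclass(frozen=True)
class LabelMap:
    """Integer label image: 0 background, otherwise one of ``class_ids``."""

    labels: np.ndarray
    class_ids: tuple[int, ...] = DEFAULT_CLASS_IDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_ids", _validate_class_ids(self.class_ids))
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"labels must be a 2-D array, got shape {labels.shape}")
        labels = labels.astype(np.int64, copy=False)
        legal = {0, *self.class_ids}
        present = set(np.unique(labels).tolist())
        illegal = present - legal
        if illegal:
            raise ValueError(f"illegal label values {sorted(illegal)}; legal: {sorted(legal)}")
        object.__setattr__(self, "labels", labels)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def foreground(self) -> np.ndarray:
        return self.labels != 0


@dataclass(frozen=True)
class RegionSet:
    """Connected components of a label map's class-agnostic foreground.

    ``component_labels`` is an ``(H, W)`` int array: 0 on background, and
    ``1 .. n_regions`` identifying each maximal connected foreground component.
    """

    component_labels: np.ndarray
    n_regions: int
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    def __len__(self) -> int:
        return self.n_regions

    def pixels(self, k: int) -> np.ndarray:
        """(N, 2) array of (row, col) coordinates of region ``k`` (1-based)."""
        if not 1 <= k <= self.n_regions:
            raise IndexError(f"region {k} out of range 1..{self.n_regions}")
        return np.argwhere(self.component_labels == k)


@dataclass
class MetricReport:
    """Per-image and aggregated Jaccard/Dice values.

    ``per_image`` records hold ``None`` for metrics undefined on that image
    (class absent from both ground truth and prediction).  Aggregate means are
    taken only over images where the metric is defined; ``defined_counts``
    reports how many images contributed to each per-class mean.
    """

    per_image: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    defined_counts: dict = field(default_factory=dict)
    class_ids: tuple[int, ...] = DEFAULT_CLASS_IDS

    def to_dict(self) -> dict:
        return {
            "class_ids": list(self.class_ids),
            "per_image": self.per_image,
            "aggregate": self.aggregate,
            "defined_counts": self.defined_counts,
        }
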