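"""Readers and writers for the on-disk formats.

* Label masks: 8-bit single-channel PNG holding literal label values
  ``{0} ∪ class_ids``; round-trips are lossless.
* Probability maps: one 16-bit grayscale PNG per class, named
  ``<stem>.class<k>.prob.png``; pixel value ``v`` encodes confidence
  ``v / 65535``, so round-trips are exact to within one quantization step
  and the endpoints 0.0 and 1.0 survive exactly.
* Dataset index: CSV with columns ``image_id, video_id, split``.
* Annotations: JSON ``{image_id, width, height, polygons: {class: [[x,y]...]}}``.

Coordinates are (x, y) = (column, row), 0-based.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .dataprep import DatasetIndex
from .types import DEFAULT_CLASS_IDS, LabelMap, ProbabilityMapSet
from .synthetic import CLASS_COLORS

PROB_SCALE = 65535


def write_label_mask(labels: LabelMap, path: str | Path) -> None:
    if labels.labels.max(initial=0) > 255:
        raise ValueError("label values exceed 8-bit range")
    iio.imwrite(Path(path), labels.labels.astype(np.uint8), extension=".png")


def read_label_mask(
    path: str | Path, class_ids: tuple[int, ...] = DEFAULT_CLASS_IDS
) -> LabelMap:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel mask, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit mask, got dtype {arr.dtype}")
    legal = {0, *class_ids}
    offending = sorted(set(np.unique(arr).tolist()) - legal)
    if offending:
        raise ValueError(f"{path}: illegal label values {offending}; legal: {sorted(legal)}")
    return LabelMap(arr.astype(np.int64), class_ids)


def prob_map_path(directory: str | Path, stem: str, class_id: int) -> Path:
    return Path(directory) / f"{stem}.class{class_id}.prob.png"


def write_probability_maps(maps: ProbabilityMapSet, directory: str | Path, stem: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid, grid in zip(maps.class_ids, maps.maps):
        q = np.round(grid * PROB_SCALE).astype(np.uint16)
        iio.imwrite(prob_map_path(directory, stem, cid), q, extension=".png")


def read_probability_maps(
    directory: str | Path, stem: str, class_ids: tuple[int, ...] = DEFAULT_CLASS_IDS
) -> ProbabilityMapSet:
    directory = Path(directory)
    missing = [c for c in class_ids if not prob_map_path(directory, stem, c).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing probability maps for classes {missing} "
            f"(expected e.g. {prob_map_path(directory, stem, missing[0]).name})"
        )
    per_class = {}
    for c in class_ids:
        arr = np.asarray(iio.imread(prob_map_path(directory, stem, c)))
        per_class[c] = arr.astype(float) / PROB_SCALE
    return ProbabilityMapSet.from_dict(per_class)


def write_color_overlay(labels: LabelMap, path: str | Path) -> None:
    """Color-coded visualization (artery red, ureter green, nerve blue)."""
    rgb = np.zeros((*labels.labels.shape, 3), dtype=np.uint8)
    for cid in labels.class_ids:
        color = CLASS_COLORS.get(cid, (255, 255, 255))
        rgb[labels.labels == cid] = color
    iio.imwrite(Path(path), rgb, extension=".png")


def write_index_csv(index: DatasetIndex, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "video_id", "split"])
        for image_id in sorted(index.records):
            video = index.records[image_id]
            split = "" if index.assignments is None else index.assignments.get(video, "")
            writer.writerow([image_id, video, split])


def read_index_csv(path: str | Path) -> DatasetIndex:
    records: dict[str, str] = {}
    assignments: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records[row["image_id"]] = row["video_id"]
            if row.get("split"):
                assignments[row["video_id"]] = row["split"]
    return DatasetIndex(records, assignments or None)


def read_annotations(path: str | Path) -> dict:
    """Boundary annotations: per-class lists of closed polygons."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("image_id", "width", "height", "polygons"):
        if key not in doc:
            raise ValueError(f"{path}: annotation document missing '{key}'")
    doc["polygons"] = {int(c): polys for c, polys in doc["polygons"].items()}
    return doc
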