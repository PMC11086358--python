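"""Synthetic surgical-scene fixtures: tubular ground truth and simulated
one-vs-all probability maps.

The generator emulates the data regime the fusion operators were designed
for: laparoscopic frames containing up to three elongated tubular structures
(uterine artery, ureter, nerve) that may co-occur, with imbalanced class
frequencies, and binary-network outputs that are noisy corruptions of the
per-class ground truth.  The noise model is compositional so each failure
mode the ensembles address can be switched on in isolation:

* **blur** — soft structure edges (spatial Gaussian filtering);
* **speckle** — isolated salt-and-pepper confidence flips;
* **confusion** — a fraction of another class's support leaks high
  confidence into this class's map (visually similar organs);
* **false blobs** — spurious high-confidence blobs on background;
* **calibration squash** — a logistic curve (normalized to fix 0 and 1)
  pushes interiors toward 1 and background toward 0.

With every rate at zero, each simulated map equals the binarized ground
truth exactly, so fusion recovers the ground truth bit-for-bit.  Everything
is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dataprep import DatasetIndex
from .types import DEFAULT_CLASS_IDS, LabelMap, ProbabilityMapSet

#: Class colors for rendered scenes and visualizations
#: (uterine artery red, ureter green, nerve blue).
CLASS_COLORS = {1: (200, 60, 50), 2: (70, 170, 80), 3: (70, 90, 200)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scene and its simulated member outputs.

    ``presence`` gives, per class, the probability that the organ appears in
    the scene (defaults mirror a strongly imbalanced regime: artery most
    frequent, nerve rarest).  Structure parameters shape the tubes; noise
    parameters shape the simulated binary-model outputs.
    """

    width: int = 256
    height: int = 192
    class_ids: tuple[int, ...] = DEFAULT_CLASS_IDS
    presence: tuple[float, ...] = (0.8, 0.45, 0.25)
    tubes_per_class: tuple[int, int] = (1, 2)
    tube_width: tuple[int, int] = (8, 22)
    curvature: float = 0.35
    blur_radius: float = 0.0
    speckle_rate: float = 0.0
    confusion_rate: float = 0.0
    false_blob_rate: float = 0.0
    calibration_sharpness: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("dimensions must be positive")
        for name in ("presence", "speckle_rate", "confusion_rate"):
            vals = np.atleast_1d(getattr(self, name)).astype(float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.presence) != len(self.class_ids):
            raise ValueError("one presence probability per class required")
        if self.false_blob_rate < 0 or self.blur_radius < 0:
            raise ValueError("rates must be non-negative")
        if self.calibration_sharpness <= 0:
            raise ValueError("calibration_sharpness must be positive")
        if self.tube_width[1] >= min(self.width, self.height):
            raise ValueError("tube width exceeds image size")


def _tube_mask(rng: np.random.Generator, cfg: ScenarioConfig) -> np.ndarray:
    """One smooth elongated tube as a boolean mask.

    A random low-curvature quadratic path is densely sampled and dilated to a
    random width, yielding the ribbon-like cross-section of a vessel, ureter
    or nerve seen through a laparoscope.
    """
    H, W = cfg.height, cfg.width
    # endpoints on opposite-ish sides so the structure is elongated
    t = np.linspace(0.0, 1.0, 4 * max(H, W))
    x0, x1 = rng.uniform(0, W - 1, 2)
    y0, y1 = rng.uniform(0, H - 1, 2)
    if abs(x1 - x0) + abs(y1 - y0) < 0.5 * (H + W) / 2:
        x1 = (x0 + W / 2) % W
        y1 = (y0 + H / 2) % H
    # quadratic Bezier with a perpendicular-ish random control point
    cx = (x0 + x1) / 2 + cfg.curvature * rng.uniform(-W, W) / 2
    cy = (y0 + y1) / 2 + cfg.curvature * rng.uniform(-H, H) / 2
    xs = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * cx + t**2 * x1
    ys = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * cy + t**2 * y1
    keep = (xs >= 0) & (xs <= W - 1) & (ys >= 0) & (ys <= H - 1)
    path = np.zeros((H, W), dtype=bool)
    path[np.round(ys[keep]).astype(int), np.round(xs[keep]).astype(int)] = True
    radius = int(rng.integers(cfg.tube_width[0], cfg.tube_width[1] + 1)) // 2
    if radius > 0:
        yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
        disk = xx**2 + yy**2 <= radius**2
        path = ndimage.binary_dilation(path, structure=disk)
    return path


def generate_scene(config: ScenarioConfig) -> tuple[np.ndarray, LabelMap]:
    """Render a scene and its exact ground-truth label map.

    Classes are drawn independently per their presence probabilities; a
    present class contributes 1+ tubes.  Later (higher-id) classes are drawn
    on top where tubes cross, like occlusion in a real scene.  Returns an
    (H, W, 3) uint8 image and the label map; identical configs give
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    labels = np.zeros((H, W), dtype=np.int64)
    sep = np.ones((3, 3), bool)  # distinct organs stay 8-disconnected
    for cid, p in zip(config.class_ids, config.presence):
        if rng.uniform() >= p:
            continue
        n_tubes = int(rng.integers(config.tubes_per_class[0], config.tubes_per_class[1] + 1))
        for _ in range(n_tubes):
            # organs are separated by tissue: reject placements whose halo
            # would touch a different class (same-class contact is fine)
            for _attempt in range(25):
                tube = _tube_mask(rng, config)
                halo = ndimage.binary_dilation(tube, sep)
                if not np.any(halo & (labels != 0) & (labels != cid)):
                    labels[tube] = cid
                    break

    # textured tissue-like background with shaded structures on top
    base = rng.uniform(90, 140)
    texture = ndimage.gaussian_filter(rng.normal(0, 18, (H, W)), 3)
    image = np.zeros((H, W, 3), dtype=float)
    image[..., 0] = base + 30 + texture
    image[..., 1] = base - 20 + texture
    image[..., 2] = base - 25 + texture
    for cid in config.class_ids:
        m = labels == cid
        if m.any():
            shade = 0.75 + 0.25 * ndimage.gaussian_filter(
                rng.uniform(0, 1, (H, W)), 5
            )
            for ch, col in enumerate(CLASS_COLORS.get(cid, (127, 127, 127))):
                image[..., ch][m] = col * shade[m]
    image = np.clip(image, 0, 255).astype(np.uint8)
    return image, LabelMap(labels, config.class_ids)


def _normalized_logistic(x: np.ndarray, sharpness: float) -> np.ndarray:
    """Logistic squash rescaled so 0 -> 0, 0.5 -> 0.5 and 1 -> 1 exactly."""
    f = 1.0 / (1.0 + np.exp(-sharpness * (x - 0.5)))
    f0 = 1.0 / (1.0 + np.exp(sharpness * 0.5))
    f1 = 1.0 / (1.0 + np.exp(-sharpness * 0.5))
    return (f - f0) / (f1 - f0)


def simulate_probability_maps(
    gt: LabelMap,
    config: ScenarioConfig,
    member_noise: dict[int, float] | None = None,
) -> ProbabilityMapSet:
    """Corrupt the per-class ground truth into plausible member outputs.

    ``member_noise`` optionally scales the false-blob rate per class id, so
    one member can be made markedly noisier than the rest (the situation
    down-weighting is meant to repair).  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng((config.seed, 0x9E3779B9))
    H, W = gt.height, gt.width
    supports = {c: (gt.labels == c).astype(float) for c in gt.class_ids}
    maps = {}
    for c in gt.class_ids:
        m = supports[c].copy()

        if config.confusion_rate > 0:
            # visually similar organs: leak confidence from other classes
            for other in gt.class_ids:
                if other == c:
                    continue
                leak = (supports[other] > 0) & (
                    rng.uniform(size=(H, W)) < config.confusion_rate
                )
                m[leak] = np.maximum(m[leak], rng.uniform(0.55, 1.0, leak.sum()))
            # and jitter the true support so leaked confidence can win
            on = supports[c] > 0
            m[on] = np.minimum(m[on], rng.uniform(0.7, 1.0, int(on.sum())))

        if config.blur_radius > 0:
            m = ndimage.gaussian_filter(m, config.blur_radius)

        if config.speckle_rate > 0:
            flip = rng.uniform(size=(H, W)) < config.speckle_rate
            m[flip] = rng.uniform(0.0, 1.0, int(flip.sum()))

        blob_rate = config.false_blob_rate * (
            1.0 if member_noise is None else member_noise.get(c, 1.0)
        )
        if blob_rate > 0:
            for _ in range(rng.poisson(blob_rate)):
                by = rng.uniform(0, H - 1)
                bx = rng.uniform(0, W - 1)
                r = rng.uniform(2, 8)
                yy, xx = np.ogrid[:H, :W]
                blob = ((xx - bx) ** 2 + (yy - by) ** 2) <= r**2
                blob &= gt.labels == 0
                m[blob] = np.maximum(m[blob], rng.uniform(0.55, 0.95, int(blob.sum())))

        noisy = (
            config.blur_radius > 0
            or config.speckle_rate > 0
            or config.confusion_rate > 0
            or blob_rate > 0
        )
        if noisy:
            m = _normalized_logistic(np.clip(m, 0.0, 1.0), config.calibration_sharpness)
        maps[c] = np.clip(m, 0.0, 1.0)
    return ProbabilityMapSet.from_dict(maps)


@dataclass
class SyntheticDataset:
    """In-memory fixture tree produced by :func:`generate_dataset`."""

    index: DatasetIndex
    images: dict[str, np.ndarray] = field(default_factory=dict)
    masks: dict[str, LabelMap] = field(default_factory=dict)
    map_sets: dict[str, ProbabilityMapSet] = field(default_factory=dict)


def generate_dataset(
    n_videos: int,
    frames_per_video: int,
    config: ScenarioConfig | None = None,
) -> SyntheticDataset:
    """A multi-video fixture with per-video correlated geometry.

    Frames of one "video" share a geometry seed (organ layout changes only
    slightly within a video, which is why splits must group by video), while
    the noise realization differs frame to frame.  Byte-identical for
    identical arguments.
    """
    if n_videos <= 0 or frames_per_video <= 0:
        raise ValueError("n_videos and frames_per_video must be positive")
    cfg = config or ScenarioConfig()
    master = np.random.default_rng(cfg.seed)
    records: dict[str, str] = {}
    ds = SyntheticDataset(DatasetIndex(records))
    for v in range(n_videos):
        video_id = f"video_{v:03d}"
        geometry_seed = int(master.integers(0, 2**31 - 1))
        for f in range(frames_per_video):
            image_id = f"{video_id}_frame_{f:03d}"
            # same geometry seed per video; tiny per-frame perturbation comes
            # from the frame index folded into the noise stream only
            frame_cfg = replace(cfg, seed=geometry_seed)
            image, gt = generate_scene(frame_cfg)
            noise_cfg = replace(cfg, seed=geometry_seed + f + 1)
            pmaps = simulate_probability_maps(gt, noise_cfg)
            records[image_id] = video_id
            ds.images[image_id] = image
            ds.masks[image_id] = gt
            ds.map_sets[image_id] = pmaps
    return ds
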