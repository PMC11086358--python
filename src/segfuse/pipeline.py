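"""Pipeline orchestration: configuration, staged execution, run manifest."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__, fusion, io, metrics
from .dataprep import group_split, slice_crops
from .synthetic import ScenarioConfig, generate_dataset
from .types import ClassWeights, DEFAULT_CLASS_IDS

METHODS = ("pixel", "pixel-weighted", "region", "region-weighted")


@dataclass
class RunConfig:
    """Configuration of one fusion/evaluation run."""

    method: str = "region"
    class_ids: tuple[int, ...] = DEFAULT_CLASS_IDS
    weights: tuple[float, ...] | None = None
    threshold: float = 0.5
    connectivity: int = 8
    seed: int = 0
    in_dir: str | None = None
    out_dir: str | None = None
    force: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if "weighted" in self.method and self.weights is None:
            raise ValueError(f"method {self.method!r} requires weights")


def fuse_maps(maps, config: RunConfig):
    """Dispatch one ProbabilityMapSet through the configured operator."""
    w = ClassWeights(config.weights) if config.weights is not None else None
    if config.method == "pixel":
        return fusion.fuse_pixelwise(maps, threshold=config.threshold)
    if config.method == "pixel-weighted":
        return fusion.fuse_pixelwise_weighted(maps, w, threshold=config.threshold)
    if config.method == "region":
        return fusion.fuse_regionwise(
            maps, threshold=config.threshold, connectivity=config.connectivity
        )
    return fusion.fuse_regionwise_weighted(
        maps, w, threshold=config.threshold, connectivity=config.connectivity
    )


@dataclass
class Manifest:
    """Reproducibility record written next to every run's outputs."""

    config: dict
    version: str = __version__
    python: str = field(default_factory=platform.python_version)
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def record(self, name: str, started: float, **extra) -> None:
        self.stages.append(
            {"stage": name, "seconds": round(time.perf_counter() - started, 4), **extra}
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(
    config: RunConfig,
    *,
    simulate: dict | None = None,
    evaluate: bool = True,
) -> tuple[int, Manifest]:
    """Chain simulate -> fuse -> eval, writing artifacts under ``out_dir``.

    When ``simulate`` is given (keys ``n_videos``, ``frames_per_video`` and
    optional ScenarioConfig overrides), a synthetic fixture tree is generated
    first; otherwise probability maps and ground truth are read from
    ``in_dir``.  Returns (exit status, manifest); status 0 iff no stage
    errored, with partial outputs retained on failure.
    """
    manifest = Manifest(config=asdict(config))
    out = Path(config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")

    try:
        if simulate is not None:
            t0 = time.perf_counter()
            sim = dict(simulate)
            n_videos = sim.pop("n_videos", 4)
            frames = sim.pop("frames_per_video", 3)
            scfg = ScenarioConfig(seed=config.seed, class_ids=config.class_ids, **sim)
            ds = generate_dataset(n_videos, frames, scfg)
            (out / "masks").mkdir(exist_ok=True)
            (out / "probs").mkdir(exist_ok=True)
            for image_id, gt in ds.masks.items():
                io.write_label_mask(gt, out / "masks" / f"{image_id}.png")
                io.write_probability_maps(ds.map_sets[image_id], out / "probs", image_id)
            io.write_index_csv(ds.index, out / "index.csv")
            stems = sorted(ds.masks)
            gt_dir, prob_dir = out / "masks", out / "probs"
            manifest.record("simulate", t0, images=len(stems))
        else:
            if config.in_dir is None:
                raise ValueError("in_dir required when not simulating")
            gt_dir = Path(config.in_dir) / "masks"
            prob_dir = Path(config.in_dir) / "probs"
            stems = sorted(p.stem for p in gt_dir.glob("*.png"))

        t0 = time.perf_counter()
        (out / "pred").mkdir(exist_ok=True)
        preds = {}
        for stem in stems:
            maps = io.read_probability_maps(prob_dir, stem, config.class_ids)
            pred = fuse_maps(maps, config)
            preds[stem] = pred
            io.write_label_mask(pred, out / "pred" / f"{stem}.png")
        manifest.record("fuse", t0, method=config.method, images=len(stems))

        if evaluate:
            t0 = time.perf_counter()
            pairs = [
                (io.read_label_mask(gt_dir / f"{stem}.png", config.class_ids), preds[stem])
                for stem in stems
            ]
            report = metrics.evaluate_dataset(pairs, config.class_ids, stems)
            with open(out / "metrics.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            manifest.record("eval", t0, images=len(pairs))
        status = 0
    except Exception as exc:  # noqa: BLE001 - manifest records the failure point
        manifest.failed_stage = f"{type(exc).__name__}: {exc}"
        status = 1

    manifest.write(manifest_path)
    return status, manifest
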