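"""End-to-end orchestration: synth → correct → train → predict → measure
→ stats → validate, from a single config with one master seed.

Every random draw is seeded from the master seed via per-stage derived
seeds (``numpy.random.SeedSequence``), so stage-level reruns are stable
and a full rerun with the same config reproduces every output byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .classify import PixelClassifier, train_multi
from .containers import Image, LabelMask
from .measure import erode_objects, measure_all, segment
from .preprocess import correct_image
from .stats import histogram, number_summary, summarize
from .synth import GroundTruth, SceneSpec, generate_scene, generate_scribbles
from .validate import agreement_summary, match_objects, validation_report

logger = logging.getLogger("agglomsizer")

STAGES = ("synth", "correct", "train", "predict", "measure", "stats", "validate")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    When the ``synth`` stage is enabled, ``scene`` and ``n_images``
    drive generation and ground truth enables training scribbles and
    validation. With ``synth`` disabled, ``images_dir`` supplies input
    TIFFs and ``scribbles_csv`` the training labels.
    """

    out_dir: str = "run"
    scene: SceneSpec = field(default_factory=SceneSpec)
    n_images: int = 8
    images_dir: str | None = None
    scribbles_csv: str | None = None
    pixel_size: float | None = None  # overrides TIFF metadata when loading
    train_fraction: float = 0.1  # fraction of images scribbled for training
    scribble_fraction: float = 0.02
    feature_scales: tuple[float, ...] = (0.7, 1.0, 1.6, 3.5, 5.0, 10.0)
    n_estimators: int = 100
    threshold: float = 0.5
    erode_px: int = 1
    min_size: int = 4
    bin_width: float = 50.0
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages in config: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if not (0 < self.threshold < 1):
            raise ConfigError("threshold must be in (0, 1)")
        if self.erode_px < 0 or self.min_size < 0 or self.n_images < 0:
            raise ConfigError("erode_px, min_size and n_images must be non-negative")
        if not (0 < self.train_fraction <= 1) or not (0 < self.scribble_fraction <= 1):
            raise ConfigError("train_fraction and scribble_fraction must be in (0, 1]")

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["scene"] = self.scene.to_dict()
        d["feature_scales"] = list(self.feature_scales)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "scene" in d and isinstance(d["scene"], dict):
            d["scene"] = SceneSpec.from_dict(d["scene"])
        if "feature_scales" in d:
            d["feature_scales"] = tuple(d["feature_scales"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Stable per-stage, per-item seed below 2^31."""
    ss = np.random.SeedSequence([int(master), STAGES.index(stage), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order and write a run manifest.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    A stage failure raises :class:`StageError` after writing a FAILED
    marker; partial outputs are retained.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": {**dataclasses.asdict(cfg), "scene": cfg.scene.to_dict()},
        "stages": [],
    }
    state: dict[str, Any] = {"images": [], "truths": [], "probmaps": [],
                             "masks": [], "model": None, "measurements": None}
    current = "setup"
    try:
        for stage in STAGES:
            if not cfg.stages.get(stage, True):
                logger.info("stage %s skipped", stage)
                continue
            current = stage
            t0 = time.perf_counter()
            info = _STAGE_FUNCS[stage](cfg, state, out)
            manifest["stages"].append({
                "name": stage,
                "seconds": round(time.perf_counter() - t0, 3),
                **(info or {}),
            })
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as fh:
            fh.write(f"stage {current}: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(current, str(exc)) from exc
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# -- stages ------------------------------------------------------------


def _stage_synth(cfg: PipelineConfig, state: dict, out: str) -> dict:
    d = os.path.join(out, "synth")
    os.makedirs(d, exist_ok=True)
    for i in range(cfg.n_images):
        spec = dataclasses.replace(cfg.scene, seed=derive_seed(cfg.seed, "synth", i))
        img, gt = generate_scene(spec, identifier=f"scene_{i:03d}")
        state["images"].append(img)
        state["truths"].append(gt)
        aio.write_image_tiff(os.path.join(d, f"{img.identifier}.tif"), img)
        aio.write_class_map_png(os.path.join(d, f"{img.identifier}_classes.png"),
                                gt.class_map)
        aio.write_object_table_csv(os.path.join(d, f"{img.identifier}_objects.csv"),
                                   gt.object_table)
    return {"n_images": cfg.n_images,
            "n_objects_true": int(sum(gt.n_objects for gt in state["truths"]))}


def _load_images(cfg: PipelineConfig, state: dict) -> None:
    if state["images"]:
        return
    if not cfg.images_dir:
        raise ValueError("no images: enable the synth stage or set images_dir")
    if not os.path.isdir(cfg.images_dir):
        raise ValueError(f"images_dir does not exist: {cfg.images_dir}")
    for path in aio.list_tiffs(cfg.images_dir):
        state["images"].append(aio.read_image_tiff(path, pixel_size=cfg.pixel_size))


def _stage_correct(cfg: PipelineConfig, state: dict, out: str) -> dict:
    _load_images(cfg, state)
    d = os.path.join(out, "corrected")
    os.makedirs(d, exist_ok=True)
    corrected = []
    for img in state["images"]:
        fixed = correct_image(img)
        fixed = Image(fixed.pixels, fixed.pixel_size, img.identifier)
        corrected.append(fixed)
        aio.write_image_tiff(os.path.join(d, f"{img.identifier}.tif"), fixed)
    state["images"] = corrected
    return {"n_images": len(corrected)}


def _stage_train(cfg: PipelineConfig, state: dict, out: str) -> dict:
    _load_images(cfg, state)
    items = []
    if state["truths"]:
        n = len(state["images"])
        n_train = max(1, int(np.ceil(cfg.train_fraction * n)))
        rng = np.random.default_rng(derive_seed(cfg.seed, "train"))
        chosen = sorted(rng.choice(n, size=min(n_train, n), replace=False).tolist())
        for i in chosen:
            scr = generate_scribbles(state["truths"][i], cfg.scribble_fraction,
                                     seed=derive_seed(cfg.seed, "train", i + 1),
                                     image_id=state["images"][i].identifier)
            aio.write_scribbles_csv(
                os.path.join(out, f"scribbles_{state['images'][i].identifier}.csv"), scr)
            items.append((state["images"][i], scr))
    else:
        if not cfg.scribbles_csv:
            raise ValueError("training requires scribbles: set scribbles_csv "
                             "(no ground truth available)")
        if not os.path.isfile(cfg.scribbles_csv):
            raise ValueError(f"scribbles file does not exist: {cfg.scribbles_csv}")
        scr = aio.read_scribbles_csv(cfg.scribbles_csv)
        target = next((im for im in state["images"] if im.identifier == scr.image_id),
                      state["images"][0])
        items.append((target, scr))
    model = train_multi(items, seed=derive_seed(cfg.seed, "train"),
                        feature_scales=tuple(cfg.feature_scales),
                        n_estimators=cfg.n_estimators)
    model.save(os.path.join(out, "model.joblib"))
    state["model"] = model
    return {"n_training_images": len(items),
            "n_labels": model.n_labels_,
            "train_accuracy": model.train_accuracy_}


def _stage_predict(cfg: PipelineConfig, state: dict, out: str) -> dict:
    _load_images(cfg, state)
    model = state["model"]
    if model is None:
        path = os.path.join(out, "model.joblib")
        if not os.path.isfile(path):
            raise ValueError("no trained model: enable the train stage first")
        model = PixelClassifier.load(path)
        state["model"] = model
    d = os.path.join(out, "probability")
    os.makedirs(d, exist_ok=True)
    from .classify import batch_predict
    maps = batch_predict(model, state["images"])
    for pm in maps:
        aio.write_probability_tiff(os.path.join(d, f"{pm.image_id}.tif"), pm)
    state["probmaps"] = maps
    return {"n_maps": len(maps)}


def _stage_measure(cfg: PipelineConfig, state: dict, out: str) -> dict:
    if not state["probmaps"]:
        raise ValueError("no probability maps: enable the predict stage first")
    d = os.path.join(out, "labels")
    os.makedirs(d, exist_ok=True)
    tables = []
    masks = []
    for img, pm in zip(state["images"], state["probmaps"]):
        mask = segment(pm, threshold=cfg.threshold, min_size=cfg.min_size)
        mask = erode_objects(mask, n_px=cfg.erode_px)
        masks.append(mask)
        aio.write_labels_tiff(os.path.join(d, f"{pm.image_id}.tif"), mask)
        tables.append(measure_all(mask, img))
    state["masks"] = masks
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=aio.MEASUREMENT_COLUMNS)
    state["measurements"] = table
    aio.write_measurements_csv(os.path.join(out, "measurements.csv"), table)
    return {"n_objects": int(len(table))}


def _stage_stats(cfg: PipelineConfig, state: dict, out: str) -> dict:
    table = state["measurements"]
    if table is None:
        raise ValueError("no measurements: enable the measure stage first")
    if len(table) == 0:
        summary = {"n": 0}
        pd.DataFrame([summary]).to_csv(os.path.join(out, "summary.csv"), index=False)
        return summary
    diam = table["feret_nm"].to_numpy()
    summary = summarize(diam)
    pd.DataFrame([{"group": "all", **summary}]).to_csv(
        os.path.join(out, "summary.csv"), index=False)
    edges, counts = histogram(number_summary(diam), cfg.bin_width)
    pd.DataFrame({"bin_lo_nm": edges[:-1], "bin_hi_nm": edges[1:],
                  "count": counts}).to_csv(
        os.path.join(out, "histogram.csv"), index=False)
    return {k: (round(v, 3) if isinstance(v, float) else v) for k, v in summary.items()}


def _stage_validate(cfg: PipelineConfig, state: dict, out: str) -> dict:
    if not state["truths"]:
        logger.info("validate: no ground truth available, stage is a no-op")
        return {"skipped": "no ground truth"}
    if not state["masks"]:
        raise ValueError("no segmentation masks: enable the measure stage first")
    ious = []
    n_ref = n_test = n_pairs = 0
    for gt, mask in zip(state["truths"], state["masks"]):
        ref = LabelMask(gt.label_map, provenance="ground_truth")
        matches = match_objects(ref, mask)
        ious.extend(matches.ious.tolist())
        n_ref += matches.n_ref
        n_test += matches.n_test
        n_pairs += len(matches.pairs)
    mean_iou = float(np.mean(ious)) if ious else float("nan")
    sd_iou = float(np.std(ious, ddof=1)) if len(ious) > 1 else 0.0
    ratio = n_test / n_ref if n_ref else float("nan")
    report = {
        "n_true_objects": n_ref, "n_machine_objects": n_test,
        "count_ratio": round(ratio, 4), "n_scored": n_pairs,
        "mean_iou": round(mean_iou, 4), "sd_iou": round(sd_iou, 4),
    }
    pd.DataFrame([report]).to_csv(os.path.join(out, "validation.csv"), index=False)
    with open(os.path.join(out, "validation.txt"), "w") as fh:
        fh.write(json.dumps(report, indent=2) + "\n")
    return report


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "correct": _stage_correct,
    "train": _stage_train,
    "predict": _stage_predict,
    "measure": _stage_measure,
    "stats": _stage_stats,
    "validate": _stage_validate,
}
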