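"""Shared fixtures.

The expensive artifacts (trained classifiers, predicted scenes) are
session-scoped and reused across tests; everything is generated
programmatically from seeded specs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from agglomsizer.classify import train_multi
from agglomsizer.containers import LabelMask
from agglomsizer.measure import erode_objects, measure_all, segment
from agglomsizer.pipeline import PipelineConfig
from agglomsizer.preprocess import correct_image
from agglomsizer.synth import SceneSpec, generate_scene, generate_scribbles
from agglomsizer.validate import match_objects

#: stock study conditions: dispersed ~400 nm agglomerates at 15 nm/px with
#: focal halos, vignetting and shot noise
STOCK_SPEC = SceneSpec()

#: reduced spec for contract-level (non-statistical) pipeline tests
SMALL_SPEC = SceneSpec(image_shape=(256, 256), n_agglomerates=6)


def _pipeline_run_one(master: int, n_scenes: int = 4):
    """Train on one stock scene, predict/segment/measure ``n_scenes``."""
    scenes = [generate_scene(dataclasses.replace(STOCK_SPEC, seed=1000 * master + i),
                             f"scene{i}") for i in range(n_scenes)]
    fixed = [correct_image(im) for im, _ in scenes]
    scribbles = generate_scribbles(scenes[0][1], 0.02, seed=master + 5)
    model = train_multi([(fixed[0], scribbles)], seed=master + 3)
    out = []
    for (img, gt), fx in zip(scenes, fixed):
        pm = model.predict_proba_map(fx)
        raw = segment(pm)
        eroded = erode_objects(raw, 1)
        out.append({
            "image": fx,
            "gt": gt,
            "prob": pm,
            "mask_raw": raw,
            "mask_eroded": eroded,
            "table_raw": measure_all(raw, fx),
            "table_eroded": measure_all(eroded, fx),
        })
    return {"model": model, "scenes": out}


@pytest.fixture(scope="session")
def stock_runs():
    """Three independently trained stock runs of four scenes each."""
    return [_pipeline_run_one(master) for master in (0, 1, 2)]


def feret_errors(run, which: str) -> np.ndarray:
    """Measured-minus-true Feret (nm) over greedy-matched objects."""
    errs = []
    for sc in run["scenes"]:
        gt = sc["gt"]
        mask = sc[f"mask_{which}"]
        tab = sc[f"table_{which}"]
        ref = LabelMask(gt.label_map)
        for (ri, ti, _, _, _) in match_objects(ref, mask).pairs:
            true = gt.object_table.loc[
                gt.object_table.object_id == ri, "true_feret_nm"].iloc[0]
            meas = tab.loc[tab.object_id == ti, "feret_nm"].iloc[0]
            errs.append(meas - true)
    return np.asarray(errs)


@pytest.fixture(scope="session")
def small_pipeline_config(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_small")
    return PipelineConfig(out_dir=str(out / "run"), scene=SMALL_SPEC,
                          n_images=3, seed=11)
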