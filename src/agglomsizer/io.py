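"""File-format boundary: TIFF rasters, indexed PNG label images, CSV tables.

Images travel as 16-bit grayscale TIFF, probability maps as 32-bit float
TIFF, label masks as 16-bit TIFF; ground-truth class maps as indexed PNG
(0 = background, 1 = agglomerate, 2 = salt); scribbles as ``row,col,class``
CSV or indexed PNG (0 = unlabelled, 1 = agglomerate, 2 = background).
"""

from __future__ import annotations

import os
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .containers import (
    LABEL_AGGLOMERATE,
    LABEL_BACKGROUND,
    Image,
    LabelMask,
    ProbabilityMap,
    ScribbleSet,
)

OBJECT_TABLE_COLUMNS = [
    "object_id", "centroid_row", "centroid_col", "true_feret_nm", "true_area_nm2",
]

MEASUREMENT_COLUMNS = [
    "image_id", "object_id", "feret_nm", "area_nm2", "perimeter_nm",
    "form_factor", "major_nm", "minor_nm", "eqdiam_nm",
    "centroid_row", "centroid_col",
]


def write_image_tiff(path: str | os.PathLike, img: Image) -> None:
    """Write as 16-bit grayscale TIFF, clipping to the uint16 range."""
    data = np.clip(np.rint(img.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"pixel_size_nm": img.pixel_size})


def read_image_tiff(path: str | os.PathLike, pixel_size: float | None = None,
                    identifier: str | None = None) -> Image:
    """Read a grayscale TIFF; pixel size from the sidecar metadata unless given."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size_nm", 0.0))
        if pixel_size <= 0:
            raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size explicitly")
    name = identifier if identifier is not None else os.path.splitext(os.path.basename(path))[0]
    return Image(np.asarray(data, dtype=np.float64), pixel_size, name)


def write_probability_tiff(path: str | os.PathLike, prob: ProbabilityMap) -> None:
    tifffile.imwrite(path, prob.values.astype(np.float32))


def read_probability_tiff(path: str | os.PathLike, image_id: str | None = None,
                          model_id: str = "model") -> ProbabilityMap:
    data = tifffile.imread(path)
    name = image_id if image_id is not None else os.path.splitext(os.path.basename(path))[0]
    return ProbabilityMap(np.asarray(data, dtype=np.float64), image_id=name, model_id=model_id)


def write_labels_tiff(path: str | os.PathLike, mask: LabelMask) -> None:
    if mask.n_objects > 65535:
        raise ValueError("more than 65535 objects cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def read_labels_tiff(path: str | os.PathLike, connectivity: int = 8) -> LabelMask:
    data = tifffile.imread(path).astype(np.int32)
    return LabelMask(data, connectivity=connectivity, provenance=str(path))


def write_class_map_png(path: str | os.PathLike, class_map: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(class_map, dtype=np.uint8))


def read_class_map_png(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=np.uint8)


def write_scribbles_csv(path: str | os.PathLike, scribbles: ScribbleSet) -> None:
    pd.DataFrame({
        "row": scribbles.rows, "col": scribbles.cols, "class": scribbles.labels,
    }).to_csv(path, index=False)


def read_scribbles_csv(path: str | os.PathLike, image_id: str | None = None) -> ScribbleSet:
    df = pd.read_csv(path)
    name = image_id if image_id is not None else os.path.splitext(os.path.basename(path))[0]
    return ScribbleSet(df["row"].to_numpy(), df["col"].to_numpy(),
                       df["class"].to_numpy(dtype=object), image_id=name)


def write_scribbles_png(path: str | os.PathLike, scribbles: ScribbleSet,
                        shape: tuple[int, int]) -> None:
    """Indexed PNG: 0 unlabelled, 1 agglomerate, 2 background."""
    canvas = np.zeros(shape, dtype=np.uint8)
    agg = scribbles.labels == LABEL_AGGLOMERATE
    canvas[scribbles.rows[agg], scribbles.cols[agg]] = 1
    canvas[scribbles.rows[~agg], scribbles.cols[~agg]] = 2
    iio.imwrite(path, canvas)


def read_scribbles_png(path: str | os.PathLike, image_id: str | None = None) -> ScribbleSet:
    canvas = np.asarray(iio.imread(path))
    name = image_id if image_id is not None else os.path.splitext(os.path.basename(path))[0]
    rows, cols = np.nonzero(canvas)
    labels = np.where(canvas[rows, cols] == 1, LABEL_AGGLOMERATE, LABEL_BACKGROUND)
    return ScribbleSet(rows, cols, labels.astype(object), image_id=name)


def write_object_table_csv(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.loc[:, OBJECT_TABLE_COLUMNS].to_csv(path, index=False)


def read_object_table_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_measurements_csv(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.loc[:, MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def list_tiffs(directory: str | os.PathLike) -> list[str]:
    names = sorted(
        f for f in os.listdir(directory) if f.lower().endswith((".tif", ".tiff"))
    )
    return [os.path.join(directory, f) for f in names]
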