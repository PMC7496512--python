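"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* rasters are 2-D ``numpy`` arrays indexed ``[row, col]``, 0-based, origin
  at the top-left;
* physical scale is carried as ``pixel_size`` in nm per pixel;
* class labels in ground-truth class maps are ``0`` background,
  ``1`` agglomerate, ``2`` salt precipitate;
* scribble (training) labels use the two-class scheme of the workflow:
  ``"agglomerate"`` and ``"background"`` (salt is background).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CLASS_BACKGROUND = 0
CLASS_AGGLOMERATE = 1
CLASS_SALT = 2

LABEL_AGGLOMERATE = "agglomerate"
LABEL_BACKGROUND = "background"


@dataclass(frozen=True)
class Image:
    """A 2-D grayscale raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative, finite intensities (any dtype; stored
        as float64).
    pixel_size : float
        Physical size of one pixel in nm/px, strictly positive.
    identifier : str
        Source name used in provenance and error messages.
    """

    pixels: np.ndarray
    pixel_size: float
    identifier: str = "image"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"{self.identifier}: image must be 2-D, got ndim={px.ndim}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(
                f"{self.identifier}: image must be at least 16x16 px, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError(f"{self.identifier}: image contains non-finite intensities")
        if np.any(px < 0):
            raise ValueError(f"{self.identifier}: image contains negative intensities")
        if not (self.pixel_size > 0):
            raise ValueError(f"{self.identifier}: pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, suffix: str = "") -> "Image":
        return Image(pixels, self.pixel_size, self.identifier + suffix)


@dataclass(frozen=True)
class ScribbleSet:
    """Sparse two-class pixel annotations used to train the classifier."""

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray  # array of str, LABEL_AGGLOMERATE / LABEL_BACKGROUND
    image_id: str = "image"

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.intp)
        cols = np.asarray(self.cols, dtype=np.intp)
        labels = np.asarray(self.labels, dtype=object)
        if not (rows.shape == cols.shape == labels.shape):
            raise ValueError("rows, cols and labels must have identical shapes")
        bad = set(labels) - {LABEL_AGGLOMERATE, LABEL_BACKGROUND}
        if bad:
            raise ValueError(f"unknown scribble labels: {sorted(bad)}")
        # a coordinate may be listed once only; conflicting duplicates are an error
        coords = rows * (cols.max(initial=0) + 1) + cols if rows.size else rows
        if rows.size and np.unique(coords).size != coords.size:
            raise ValueError("duplicate scribble coordinates")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.rows.size)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def check_bounds(self, shape: tuple[int, int]) -> None:
        if len(self) == 0:
            return
        if (
            self.rows.min() < 0
            or self.cols.min() < 0
            or self.rows.max() >= shape[0]
            or self.cols.max() >= shape[1]
        ):
            raise ValueError(
                f"scribbles for {self.image_id!r} fall outside image of shape {shape}"
            )


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel probability of the agglomerate class, in [0, 1]."""

    values: np.ndarray
    image_id: str = "image"
    model_id: str = "model"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1:
            raise ValueError("probabilities must be finite and within [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel object ids (0 = background), ids contiguous 1..N.

    ``dropped_ids`` records objects removed by a processing step (e.g.
    emptied by erosion), for logging.
    """

    labels: np.ndarray
    connectivity: int = 8
    provenance: str = ""
    dropped_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        lab = lab.astype(np.int32, copy=False)
        ids = np.unique(lab)
        ids = ids[ids > 0]
        n = ids.size
        if n and (ids.min() != 1 or ids.max() != n):
            raise ValueError("object ids must be contiguous 1..N")
        object.__setattr__(self, "labels", lab)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def pixels_of(self, object_id: int) -> np.ndarray:
        """(k, 2) array of (row, col) pixel coordinates of one object."""
        rc = np.argwhere(self.labels == object_id)
        return rc


def relabel_sequential_mask(labels: np.ndarray, connectivity: int = 8,
                            provenance: str = "", dropped: Sequence[int] = ()) -> LabelMask:
    """Map arbitrary positive ids onto contiguous 1..N preserving order."""
    lab = np.asarray(labels).astype(np.int32, copy=True)
    ids = np.unique(lab)
    ids = ids[ids > 0]
    lut = np.zeros(int(ids.max(initial=0)) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    out = np.where(lab > 0, lut[np.clip(lab, 0, None)], 0).astype(np.int32)
    return LabelMask(out, connectivity=connectivity, provenance=provenance,
                     dropped_ids=tuple(int(d) for d in dropped))
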