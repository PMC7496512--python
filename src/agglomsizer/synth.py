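"""Synthetic dark-field STEM scenes with full ground truth.

Emulates the image content of dispersion micrographs of nanoparticle
agglomerates on a carbon support: bright quasi-circular agglomerates
(unions of 1-6 overlapping disks; a single disk is the single-particle
case), a raised-intensity focal halo annulus hugging each object,
mid-intensity salt precipitates with high-frequency speckle texture,
a finite probe size (Gaussian blur), smooth multiplicative uneven
illumination and additive detector noise. Ground truth records the
pre-blur, pre-noise geometry of every object.

All randomness flows from one ``numpy`` Generator seeded by
``SceneSpec.seed``; identical specs give byte-identical scenes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk as disk_footprint

from .containers import (
    CLASS_AGGLOMERATE,
    CLASS_BACKGROUND,
    CLASS_SALT,
    LABEL_AGGLOMERATE,
    LABEL_BACKGROUND,
    Image,
    ScribbleSet,
)
from .measure import feret_diameter

_STRUCT_8 = np.ones((3, 3), dtype=bool)


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap (scene too dense)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``diameter_law`` is either ``{"kind": "lognormal", "median_nm": m,
    "sigma": s}`` or ``{"kind": "fixed", "diameters_nm": [...]}`` (the
    fixed list must have ``n_agglomerates`` entries). Intensities are
    gray levels on the 16-bit scale. ``illumination_gradient`` is the
    relative amplitude of the multiplicative shading field;
    ``psf_sigma`` the Gaussian probe blur in px applied to the clean
    render before noise.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 15.0
    n_agglomerates: int = 18
    diameter_law: dict[str, Any] = field(
        default_factory=lambda: {"kind": "lognormal", "median_nm": 400.0, "sigma": 0.35})
    disks_per_agglomerate: tuple[int, int] = (1, 6)
    background_level: float = 1000.0
    agglomerate_intensity: float = 20000.0
    halo_width: int = 2
    halo_intensity_fraction: float = 0.3
    n_salt: int = 0
    salt_intensity: float = 17000.0
    salt_speckle_sigma: float = 0.25
    salt_diameter_nm: tuple[float, float] = (250.0, 700.0)
    illumination_gradient: float = 0.2
    noise_sigma: float = 300.0
    psf_sigma: float = 1.0
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"zero-size image: shape {self.image_shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_agglomerates < 0 or self.n_salt < 0:
            raise ValueError("object counts must be non-negative")
        if self.halo_width < 0:
            raise ValueError("halo_width must be >= 0")
        if not (0 <= self.halo_intensity_fraction <= 1):
            raise ValueError("halo_intensity_fraction must be in [0, 1]")
        if not (0 <= self.illumination_gradient < 1):
            raise ValueError("illumination_gradient must be in [0, 1)")
        if self.noise_sigma < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sigma and psf_sigma must be >= 0")
        law = self.diameter_law
        if law.get("kind") == "fixed":
            diams = np.asarray(law["diameters_nm"], dtype=float)
            if len(diams) != self.n_agglomerates:
                raise ValueError(
                    f"fixed diameter list has {len(diams)} entries for "
                    f"{self.n_agglomerates} agglomerates")
            if np.any(diams <= 0):
                raise ValueError("diameters must be strictly positive")
        elif law.get("kind") == "lognormal":
            if law["median_nm"] <= 0 or law["sigma"] < 0:
                raise ValueError("lognormal diameter law needs median_nm > 0, sigma >= 0")
        else:
            raise ValueError(f"unknown diameter law: {law!r}")
        lo, hi = self.disks_per_agglomerate
        if not (1 <= lo <= hi):
            raise ValueError("disks_per_agglomerate must satisfy 1 <= min <= max")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["disks_per_agglomerate"] = list(self.disks_per_agglomerate)
        d["salt_diameter_nm"] = list(self.salt_diameter_nm)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SceneSpec":
        d = dict(d)
        for key in ("image_shape", "disks_per_agglomerate", "salt_diameter_nm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SceneSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Pre-noise geometry of one scene.

    ``class_map``: 0 background / 1 agglomerate / 2 salt;
    ``label_map``: per-pixel agglomerate object id (0 = none);
    ``halo_mask``: the halo annuli (ambiguous pixels, never scribbled);
    ``object_table``: per-object centroid (px), true Feret (nm, corner
    convention on the rasterized object) and true area (nm²).
    """

    class_map: np.ndarray
    label_map: np.ndarray
    halo_mask: np.ndarray
    object_table: pd.DataFrame
    pixel_size: float
    halo_width: int = 2

    @property
    def n_objects(self) -> int:
        return len(self.object_table)


def _sample_diameters(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.diameter_law
    if law["kind"] == "fixed":
        return np.asarray(law["diameters_nm"], dtype=float)
    z = rng.standard_normal(spec.n_agglomerates)
    return law["median_nm"] * np.exp(law["sigma"] * z)


def _agglomerate_stamp(diameter_px: float, n_disks: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Rasterize one agglomerate as a union of overlapping disks.

    The first disk has the nominal diameter; satellites are smaller and
    placed close enough that the union stays connected.
    """
    r0 = max(diameter_px / 2.0, 1.0)
    disks = [(0.0, 0.0, r0)]
    for _ in range(n_disks - 1):
        # satellites attach to the primary disk so cluster extent stays
        # bounded (~2.2 r0) and dense scenes remain placeable
        ri = r0 * rng.uniform(0.35, 0.75)
        dist = (r0 + ri) * rng.uniform(0.35, 0.8)
        ang = rng.uniform(0, 2 * np.pi)
        disks.append((dist * np.sin(ang), dist * np.cos(ang), ri))
    arr = np.array(disks)
    rmin = np.floor((arr[:, 0] - arr[:, 2]).min())
    rmax = np.ceil((arr[:, 0] + arr[:, 2]).max())
    cmin = np.floor((arr[:, 1] - arr[:, 2]).min())
    cmax = np.ceil((arr[:, 1] + arr[:, 2]).max())
    h, w = int(rmax - rmin) + 1, int(cmax - cmin) + 1
    rr, cc = np.mgrid[0:h, 0:w]
    # pixel centers at index + 0.5, shifted into disk coordinates
    yc = rr + 0.5 + rmin
    xc = cc + 0.5 + cmin
    stamp = np.zeros((h, w), dtype=bool)
    for dy, dx, r in disks:
        stamp |= (yc - dy) ** 2 + (xc - dx) ** 2 <= r * r
    # keep the component containing the primary disk (paranoia: unions are
    # connected by construction, but rasterization of grazing overlaps can split)
    lab, _ = ndimage.label(stamp, structure=_STRUCT_8)
    centre = (int(np.clip(-rmin, 0, h - 1)), int(np.clip(-cmin, 0, w - 1)))
    keep = lab[centre]
    if keep == 0:
        keep = np.argmax(np.bincount(lab[lab > 0])) if stamp.any() else 0
    return lab == keep


def _salt_stamp(diameter_px: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one salt precipitate as a random star-convex polygon."""
    k = int(rng.integers(5, 10))
    ang = np.sort(rng.uniform(0, 2 * np.pi, k))
    rad = diameter_px / 2.0 * rng.uniform(0.6, 1.0, k)
    rr = rad * np.sin(ang)
    cc = rad * np.cos(ang)
    rr -= rr.min()
    cc -= cc.min()
    h = int(np.ceil(rr.max())) + 1
    w = int(np.ceil(cc.max())) + 1
    pr, pc = draw_polygon(rr, cc, shape=(h, w))
    stamp = np.zeros((h, w), dtype=bool)
    stamp[pr, pc] = True
    return stamp


def _place(stamp: np.ndarray, occupied: np.ndarray, margin: int,
           rng: np.random.Generator, max_attempts: int, what: str) -> tuple[int, int]:
    """Rejection-sample a top-left position where ``stamp`` (plus a margin)
    avoids all previously occupied pixels."""
    H, W = occupied.shape
    h, w = stamp.shape
    if h > H or w > W:
        raise PlacementError(
            f"{what} of size {stamp.shape} does not fit in image {occupied.shape}")
    grown = ndimage.binary_dilation(np.pad(stamp, margin), structure=_STRUCT_8,
                                    iterations=margin) if margin > 0 else stamp
    gh, gw = grown.shape
    for _ in range(max_attempts):
        r = int(rng.integers(0, H - h + 1))
        c = int(rng.integers(0, W - w + 1))
        r0, c0 = r - margin, c - margin
        rs = slice(max(r0, 0), min(r0 + gh, H))
        cs = slice(max(c0, 0), min(c0 + gw, W))
        gsub = grown[rs.start - r0: rs.stop - r0, cs.start - c0: cs.stop - c0]
        if not (occupied[rs, cs] & gsub).any():
            return r, c
    raise PlacementError(
        f"could not place {what} after {max_attempts} attempts: "
        "scene too dense for non-overlapping objects; reduce counts or sizes")


def _illumination_field(shape: tuple[int, int], amplitude: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative shading: random degree-2 polynomial with
    max relative deviation exactly ``amplitude``."""
    coeff = rng.uniform(-1.0, 1.0, 5)
    if amplitude == 0:
        return np.ones(shape)
    u = np.linspace(-1.0, 1.0, shape[0])[:, None]
    v = np.linspace(-1.0, 1.0, shape[1])[None, :]
    poly = (coeff[0] * u + coeff[1] * v + coeff[2] * (u * u - 1 / 3)
            + coeff[3] * (v * v - 1 / 3) + coeff[4] * u * v)
    peak = np.abs(poly).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * poly / peak


def _object_table(label_map: np.ndarray, pixel_size: float) -> pd.DataFrame:
    records = []
    for obj_id, sl in enumerate(ndimage.find_objects(label_map), start=1):
        if sl is None:
            continue
        local = np.argwhere(label_map[sl] == obj_id)
        rc = local + np.array([sl[0].start, sl[1].start])
        records.append({
            "object_id": obj_id,
            "centroid_row": float(rc[:, 0].mean()),
            "centroid_col": float(rc[:, 1].mean()),
            "true_feret_nm": feret_diameter(rc, pixel_size),
            "true_area_nm2": float(len(rc)) * pixel_size**2,
        })
    return pd.DataFrame.from_records(
        records, columns=["object_id", "centroid_row", "centroid_col",
                          "true_feret_nm", "true_area_nm2"])


def generate_scene(spec: SceneSpec, identifier: str = "scene") -> tuple[Image, GroundTruth]:
    """Render one scene and its ground truth.

    Objects are placed by rejection sampling with overlap forbidden
    (halo annuli included in the exclusion zone) so per-object truth is
    unambiguous. Render order: flat background, halo annuli, agglomerate
    disks, textured salt; then probe blur, multiplicative illumination
    and additive Gaussian noise. Ground truth reflects the clean,
    pre-blur geometry.
    """
    # independent child streams so that ablations (e.g. the same scene
    # without objects) keep identical illumination and noise fields
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng, rng_texture, rng_illum, rng_noise = (np.random.default_rng(s) for s in ss)
    H, W = spec.image_shape
    label_map = np.zeros((H, W), dtype=np.int32)
    class_map = np.zeros((H, W), dtype=np.uint8)
    occupied = np.zeros((H, W), dtype=bool)
    # objects must stay resolvable: separation exceeds the combined halo and
    # probe-blur footprint of both neighbours, else halos merge and
    # per-object truth becomes ambiguous
    margin = 2 * (spec.halo_width + int(np.ceil(2 * spec.psf_sigma))) + 4

    diameters = _sample_diameters(spec, rng)
    lo, hi = spec.disks_per_agglomerate
    for i, d_nm in enumerate(diameters, start=1):
        n_disks = int(rng.integers(lo, hi + 1))
        stamp = _agglomerate_stamp(d_nm / spec.pixel_size, n_disks, rng)
        r, c = _place(stamp, occupied, margin, rng, spec.max_attempts,
                      f"agglomerate {i}")
        sl = (slice(r, r + stamp.shape[0]), slice(c, c + stamp.shape[1]))
        label_map[sl][stamp] = i
        occupied[sl] |= stamp

    agg_mask = label_map > 0
    class_map[agg_mask] = CLASS_AGGLOMERATE
    if spec.halo_width > 0 and agg_mask.any():
        halo_mask = ndimage.binary_dilation(
            agg_mask, structure=disk_footprint(spec.halo_width)) & ~agg_mask
    else:
        halo_mask = np.zeros((H, W), dtype=bool)
    occupied |= halo_mask

    salt_mask = np.zeros((H, W), dtype=bool)
    for j in range(spec.n_salt):
        d_nm = rng.uniform(*spec.salt_diameter_nm)
        stamp = _salt_stamp(d_nm / spec.pixel_size, rng)
        r, c = _place(stamp, occupied, 3, rng, spec.max_attempts, f"salt {j + 1}")
        sl = (slice(r, r + stamp.shape[0]), slice(c, c + stamp.shape[1]))
        salt_mask[sl] |= stamp
        occupied[sl] |= stamp
    class_map[salt_mask] = CLASS_SALT

    # clean render
    img = np.full((H, W), spec.background_level, dtype=np.float64)
    halo_level = (spec.background_level + spec.halo_intensity_fraction
                  * (spec.agglomerate_intensity - spec.background_level))
    img[halo_mask] = halo_level
    img[agg_mask] = spec.agglomerate_intensity
    if salt_mask.any():
        speckle = 1.0 + spec.salt_speckle_sigma * rng_texture.standard_normal(
            int(salt_mask.sum()))
        img[salt_mask] = spec.salt_intensity * np.clip(speckle, 0.05, None)

    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma)
    img *= _illumination_field((H, W), spec.illumination_gradient, rng_illum)
    if spec.noise_sigma > 0:
        img += spec.noise_sigma * rng_noise.standard_normal((H, W))
    img = np.clip(img, 0.0, 65535.0)

    gt = GroundTruth(class_map=class_map, label_map=label_map, halo_mask=halo_mask,
                     object_table=_object_table(label_map, spec.pixel_size),
                     pixel_size=spec.pixel_size, halo_width=spec.halo_width)
    return Image(img, spec.pixel_size, identifier), gt


def _interior(mask: np.ndarray) -> np.ndarray:
    """Interior pixels (1-px erosion); falls back to the full class when
    erosion empties it (tiny regions)."""
    inner = ndimage.binary_erosion(mask, structure=_STRUCT_8, border_value=1)
    return inner if inner.any() else mask


def generate_scribbles(gt: GroundTruth, fraction: float, seed: int,
                       image_id: str = "scene",
                       max_per_class: int | None = 3000,
                       min_per_class: int = 150,
                       guard_px: int = 3) -> ScribbleSet:
    """Sample sparse training labels from class interiors.

    A ``fraction`` of the interior pixels of each true class is drawn
    without replacement (at least ``min_per_class`` per class where the
    pool allows — every material must be represented well enough for
    the forest to learn its texture — and at most ``max_per_class``).
    Salt interiors are labelled *background* — the
    two-class scheme of the workflow. Halo-annulus pixels are never
    sampled, and neither is a ``guard_px`` skirt around each annulus:
    both are brightened by the focal artifact and are ambiguous by
    construction.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    ambiguous = gt.halo_mask
    if guard_px > 0 and ambiguous.any():
        ambiguous = ndimage.binary_dilation(
            gt.halo_mask | (gt.label_map > 0), structure=_STRUCT_8,
            iterations=guard_px) & ~(gt.label_map > 0)
    background_pool = (gt.class_map == CLASS_BACKGROUND) & ~ambiguous
    pools = {
        LABEL_AGGLOMERATE: _interior(gt.label_map > 0),
        "plain_background": _interior(background_pool)
        if background_pool.any() else background_pool,
        "salt": _interior(gt.class_map == CLASS_SALT) if (gt.class_map == CLASS_SALT).any()
                else np.zeros_like(gt.halo_mask),
    }
    if not pools[LABEL_AGGLOMERATE].any():
        raise ValueError("no agglomerate pixels available for scribbling")
    if not pools["plain_background"].any():
        raise ValueError("no background pixels available for scribbling")

    rows_all, cols_all, labels_all = [], [], []
    for name, pool in pools.items():
        coords = np.argwhere(pool & ~gt.halo_mask)
        if len(coords) == 0:
            continue
        n = max(1, min_per_class, int(round(fraction * len(coords))))
        if max_per_class is not None:
            n = min(n, max_per_class)
        n = min(n, len(coords))
        pick = rng.choice(len(coords), size=n, replace=False)
        rows_all.append(coords[pick, 0])
        cols_all.append(coords[pick, 1])
        label = LABEL_AGGLOMERATE if name == LABEL_AGGLOMERATE else LABEL_BACKGROUND
        labels_all.append(np.full(n, label, dtype=object))
    return ScribbleSet(np.concatenate(rows_all), np.concatenate(cols_all),
                       np.concatenate(labels_all), image_id=image_id)


def simulate_blot_subsample(gt: GroundTruth, keep_prob: float, seed: int) -> GroundTruth:
    """Random object thinning emulating loss of objects during blotting.

    Each agglomerate is independently retained with probability
    ``keep_prob``; the class map, label map, halo annuli and object
    table are updated consistently and ids relabelled 1..N.
    """
    if not (0 <= keep_prob <= 1):
        raise ValueError("keep_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = gt.n_objects
    keep = rng.random(n) < keep_prob
    kept_ids = np.flatnonzero(keep) + 1

    lut = np.zeros(n + 1, dtype=np.int32)
    lut[kept_ids] = np.arange(1, len(kept_ids) + 1, dtype=np.int32)
    label_map = lut[gt.label_map]
    agg_mask = label_map > 0
    class_map = gt.class_map.copy()
    class_map[(gt.class_map == CLASS_AGGLOMERATE) & ~agg_mask] = CLASS_BACKGROUND
    if gt.halo_width > 0 and agg_mask.any():
        halo_mask = ndimage.binary_dilation(
            agg_mask, structure=disk_footprint(gt.halo_width)) & ~agg_mask
    else:
        halo_mask = np.zeros_like(gt.halo_mask)
    table = gt.object_table[gt.object_table["object_id"].isin(kept_ids)].copy()
    table["object_id"] = lut[table["object_id"].to_numpy()]
    table = table.reset_index(drop=True)
    return GroundTruth(class_map=class_map, label_map=label_map, halo_mask=halo_mask,
                       object_table=table, pixel_size=gt.pixel_size,
                       halo_width=gt.halo_width)
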