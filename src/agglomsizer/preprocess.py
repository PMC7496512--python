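"""Illumination correction: remove smooth uneven background shading.

Dark-field shading is gain-like, so the default model is multiplicative:
a smooth, strictly positive field is estimated from the image after
rank-based downweighting of bright (object) pixels, and the image is
divided by it, rescaled to preserve the median background level.

Two estimators are provided:

* ``"polynomial"`` (default): least-squares fit of a degree-2 polynomial
  surface to the non-object pixels — exact for linear ramps and
  low-order vignettes, unbiased at image edges;
* ``"gaussian"``: large-kernel Gaussian smoothing by normalized
  convolution of the masked image (scale default image_width/8).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import Image

#: fraction of pixels treated as possible objects and excluded from the fit
DEFAULT_BRIGHT_PERCENTILE = 75.0


def _background_weights(pixels: np.ndarray, bright_percentile: float) -> np.ndarray:
    thresh = np.percentile(pixels, bright_percentile)
    w = (pixels <= thresh).astype(np.float64)
    if not w.any():  # constant image: percentile == everything
        w[:] = 1.0
    return w


def _poly2_design(shape: tuple[int, int]) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, shape[0])[:, None] * np.ones((1, shape[1]))
    v = np.ones((shape[0], 1)) * np.linspace(-1.0, 1.0, shape[1])[None, :]
    cols = [np.ones(shape), u, v, u * u, v * v, u * v]
    return np.stack([c.ravel() for c in cols], axis=1)


def estimate_illumination(img: Image, smoothing_scale: float | None = None,
                          method: str = "polynomial",
                          bright_percentile: float = DEFAULT_BRIGHT_PERCENTILE) -> Image:
    """Estimate the smooth multiplicative shading field of one image.

    Bright pixels (above ``bright_percentile``) are excluded so objects
    do not inflate the field. Returns a strictly positive field of the
    same shape. ``smoothing_scale`` (px) applies to the Gaussian
    estimator; default image_width/8, must be >= 5 and smaller than the
    image.
    """
    pixels = img.pixels
    if smoothing_scale is None:
        smoothing_scale = pixels.shape[1] / 8.0
    if smoothing_scale < 5:
        raise ValueError(f"smoothing_scale must be >= 5 px, got {smoothing_scale}")
    if smoothing_scale >= min(pixels.shape):
        raise ValueError(
            f"smoothing_scale {smoothing_scale} px exceeds image size {pixels.shape}")

    w = _background_weights(pixels, bright_percentile)
    if method == "polynomial":
        X = _poly2_design(pixels.shape)
        wr = w.ravel()
        coef, *_ = np.linalg.lstsq(X * wr[:, None], pixels.ravel() * wr, rcond=None)
        field = (X @ coef).reshape(pixels.shape)
    elif method == "gaussian":
        num = ndimage.gaussian_filter(pixels * w, smoothing_scale, mode="constant")
        den = ndimage.gaussian_filter(w, smoothing_scale, mode="constant")
        field = num / np.maximum(den, 1e-12)
    else:
        raise ValueError(f"unknown illumination method {method!r}")

    floor = max(np.median(field) * 1e-3, 1e-9)
    field = np.maximum(field, floor)
    return img.with_pixels(field, suffix="|illum")


def correct_illumination(img: Image, field: Image) -> Image:
    """Divide out a shading field, preserving the median background level.

    ``out = pixels / field * median(field)`` — for a pure-background
    image ``B·field`` this returns the constant ``B·median(field)``,
    i.e. the input's median background level.
    """
    if img.shape != field.shape:
        raise ValueError(
            f"image {img.identifier!r} shape {img.shape} does not match "
            f"field shape {field.shape}")
    f = field.pixels
    if np.any(f <= 0):
        raise ValueError("illumination field must be strictly positive")
    out = img.pixels / f * np.median(f)
    return img.with_pixels(np.clip(out, 0.0, None), suffix="|corrected")


def correct_image(img: Image, smoothing_scale: float | None = None,
                  method: str = "polynomial",
                  bright_percentile: float = DEFAULT_BRIGHT_PERCENTILE) -> Image:
    """Estimate and apply the shading correction in one step."""
    field = estimate_illumination(img, smoothing_scale, method, bright_percentile)
    return correct_illumination(img, field)
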