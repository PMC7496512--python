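"""Sparse-annotation two-class pixel classification.

A multi-scale filter bank (smoothed intensity, gradient magnitude,
Laplacian, structure-tensor and Hessian eigenvalues, local variance —
the conventional interactive-pixel-classification feature family) feeds
a random forest trained on scribble annotations; prediction yields a
per-pixel probability of the agglomerate class. Texture features are
what let the forest separate speckled salt precipitates from smooth
bright agglomerates where raw intensity alone cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError

from .containers import (
    LABEL_AGGLOMERATE,
    LABEL_BACKGROUND,
    Image,
    ProbabilityMap,
    ScribbleSet,
)

#: conventional pixel-classification scale ladder, in px
DEFAULT_FEATURE_SCALES = (0.7, 1.0, 1.6, 3.5, 5.0, 10.0)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel feature vectors: array (rows, cols, n_features)."""

    data: np.ndarray
    names: tuple[str, ...]
    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != len(self.names):
            raise ValueError("feature stack shape must be rows x cols x n_features")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature stack contains non-finite values")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]  # type: ignore[return-value]

    def at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.data[rows, cols, :]


def _eigenvalues_2x2(axx: np.ndarray, axy: np.ndarray, ayy: np.ndarray):
    tr = axx + ayy
    disc = np.sqrt(np.maximum((axx - ayy) ** 2 + 4.0 * axy**2, 0.0))
    return (tr + disc) / 2.0, (tr - disc) / 2.0


def compute_features(img: Image | np.ndarray,
                     scales: tuple[float, ...] = DEFAULT_FEATURE_SCALES) -> FeatureStack:
    """Multi-scale filter bank of one image.

    Per scale σ: Gaussian-smoothed intensity, gradient magnitude,
    Laplacian, structure-tensor eigenvalues (gradient products smoothed
    at σ), Hessian eigenvalues, and local variance in a Gaussian window.
    Deterministic; on a constant image every derivative-type feature is
    zero (to floating-point tolerance) and the intensity feature equals
    the constant.
    """
    if len(scales) == 0:
        raise ValueError("scales must be a non-empty list of positive values")
    if any(s <= 0 for s in scales):
        raise ValueError(f"feature scales must be > 0, got {scales}")
    pixels = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    # derivative kernels are truncated and do not sum exactly to zero; on the
    # mean-subtracted image the constant response is exactly zero by linearity
    centered = pixels - pixels.mean()
    planes: list[np.ndarray] = []
    names: list[str] = []
    for s in scales:
        smooth = ndimage.gaussian_filter(pixels, s)
        gr = ndimage.gaussian_filter(centered, s, order=(1, 0))
        gc = ndimage.gaussian_filter(centered, s, order=(0, 1))
        grad = np.hypot(gr, gc)
        lap = ndimage.gaussian_laplace(centered, s)
        jrr = ndimage.gaussian_filter(gr * gr, s)
        jrc = ndimage.gaussian_filter(gr * gc, s)
        jcc = ndimage.gaussian_filter(gc * gc, s)
        st_hi, st_lo = _eigenvalues_2x2(jrr, jrc, jcc)
        hrr = ndimage.gaussian_filter(centered, s, order=(2, 0))
        hrc = ndimage.gaussian_filter(centered, s, order=(1, 1))
        hcc = ndimage.gaussian_filter(centered, s, order=(0, 2))
        he_hi, he_lo = _eigenvalues_2x2(hrr, hrc, hcc)
        csmooth = ndimage.gaussian_filter(centered, s)
        var = np.maximum(
            ndimage.gaussian_filter(centered * centered, s) - csmooth * csmooth, 0.0)
        planes.extend([smooth, grad, lap, st_hi, st_lo, he_hi, he_lo, var])
        names.extend(f"{feat}_s{s:g}" for feat in (
            "intensity", "gradmag", "laplacian", "st_eig_hi", "st_eig_lo",
            "hess_eig_hi", "hess_eig_lo", "variance"))
    return FeatureStack(np.stack(planes, axis=-1), tuple(names), tuple(scales))


class PixelClassifier(BaseEstimator):
    """Random-forest pixel classifier trained from sparse scribbles.

    Parameters
    ----------
    feature_scales : tuple of float
        Scale ladder of the filter bank, px.
    n_estimators : int
        Trees in the forest.
    random_state : int
        Seed for the forest; fixed seed gives identical models.
    min_labels_per_class : int
        Training floor per class.
    n_jobs : int
        Threads for fitting/prediction.

    Fitted attributes end in an underscore: ``forest_``, ``classes_``,
    ``n_labels_``, ``train_accuracy_``, ``feature_names_``.
    """

    def __init__(self, feature_scales: tuple[float, ...] = DEFAULT_FEATURE_SCALES,
                 n_estimators: int = 100, random_state: int = 0,
                 min_labels_per_class: int = 10, n_jobs: int = 1):
        self.feature_scales = feature_scales
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.min_labels_per_class = min_labels_per_class
        self.n_jobs = n_jobs

    # -- training -----------------------------------------------------
    def fit(self, image: Image | FeatureStack, scribbles: ScribbleSet) -> "PixelClassifier":
        """Fit from an image (features computed here) or a precomputed stack."""
        stack = (image if isinstance(image, FeatureStack)
                 else compute_features(image, tuple(self.feature_scales)))
        scribbles.check_bounds(stack.image_shape)
        for cls in (LABEL_AGGLOMERATE, LABEL_BACKGROUND):
            n = scribbles.count(cls)
            if n == 0:
                raise ValueError(f"no scribbles for class {cls!r}; both classes are required")
            if n < self.min_labels_per_class:
                raise ValueError(
                    f"class {cls!r} has {n} labelled pixels; "
                    f"at least {self.min_labels_per_class} are required")
        X = stack.at(scribbles.rows, scribbles.cols)
        y = np.asarray([str(l) for l in scribbles.labels])
        forest = RandomForestClassifier(
            n_estimators=self.n_estimators, class_weight="balanced",
            random_state=self.random_state, n_jobs=self.n_jobs)
        forest.fit(X, y)
        self.forest_ = forest
        self.classes_ = tuple(forest.classes_)
        self.feature_names_ = stack.names
        self.n_labels_ = {cls: int(np.sum(y == cls)) for cls in self.classes_}
        self.train_accuracy_ = float(np.mean(forest.predict(X) == y))
        return self

    @property
    def is_fitted(self) -> bool:
        return hasattr(self, "forest_")

    # -- prediction ---------------------------------------------------
    def predict_proba_map(self, image: Image | FeatureStack,
                          image_id: str | None = None) -> ProbabilityMap:
        """Per-pixel agglomerate-class probability map in [0, 1].

        The background probability is its complement: the two class
        probabilities sum to one per pixel by construction.
        """
        if not self.is_fitted:
            raise NotFittedError("PixelClassifier must be fitted before predicting")
        stack = (image if isinstance(image, FeatureStack)
                 else compute_features(image, tuple(self.feature_scales)))
        if stack.names != self.feature_names_:
            raise ValueError("feature stack does not match the trained feature bank")
        H, W = stack.image_shape
        proba = self.forest_.predict_proba(stack.data.reshape(H * W, -1))
        agg_idx = self.classes_.index(LABEL_AGGLOMERATE)
        values = proba[:, agg_idx].reshape(H, W)
        name = image_id if image_id is not None else (
            image.identifier if isinstance(image, Image) else "stack")
        return ProbabilityMap(np.clip(values, 0.0, 1.0), image_id=name,
                              model_id=f"rf{self.n_estimators}_seed{self.random_state}")

    # -- persistence --------------------------------------------------
    def save(self, path: str) -> None:
        if not self.is_fitted:
            raise NotFittedError("cannot save an unfitted PixelClassifier")
        joblib.dump({
            "format_version": MODEL_FORMAT_VERSION,
            "params": self.get_params(),
            "forest": self.forest_,
            "classes": self.classes_,
            "feature_names": self.feature_names_,
            "n_labels": self.n_labels_,
            "train_accuracy": self.train_accuracy_,
        }, path)

    @classmethod
    def load(cls, path: str) -> "PixelClassifier":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        model = cls(**payload["params"])
        model.forest_ = payload["forest"]
        model.classes_ = tuple(payload["classes"])
        model.feature_names_ = tuple(payload["feature_names"])
        model.n_labels_ = payload["n_labels"]
        model.train_accuracy_ = payload["train_accuracy"]
        return model


# -- thin functional wrappers (the train-then-batch workflow) ----------

def train(features: FeatureStack | Image, scribbles: ScribbleSet, seed: int = 0,
          **params) -> PixelClassifier:
    """Train a classifier on one image's features and scribbles."""
    return PixelClassifier(random_state=seed, **params).fit(features, scribbles)


def train_multi(items: list[tuple[Image | FeatureStack, ScribbleSet]],
                seed: int = 0, **params) -> PixelClassifier:
    """Train one classifier on scribbles pooled over several images."""
    if not items:
        raise ValueError("train_multi needs at least one (image, scribbles) pair")
    Xs, ys = [], []
    model = PixelClassifier(random_state=seed, **params)
    names = None
    for image, scribbles in items:
        stack = (image if isinstance(image, FeatureStack)
                 else compute_features(image, tuple(model.feature_scales)))
        scribbles.check_bounds(stack.image_shape)
        if names is None:
            names = stack.names
        Xs.append(stack.at(scribbles.rows, scribbles.cols))
        ys.append(np.asarray([str(l) for l in scribbles.labels]))
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    for cls in (LABEL_AGGLOMERATE, LABEL_BACKGROUND):
        n = int(np.sum(y == cls))
        if n == 0:
            raise ValueError(f"no scribbles for class {cls!r}; both classes are required")
        if n < model.min_labels_per_class:
            raise ValueError(
                f"class {cls!r} has {n} labelled pixels; "
                f"at least {model.min_labels_per_class} are required")
    forest = RandomForestClassifier(
        n_estimators=model.n_estimators, class_weight="balanced",
        random_state=model.random_state, n_jobs=model.n_jobs)
    forest.fit(X, y)
    model.forest_ = forest
    model.classes_ = tuple(forest.classes_)
    model.feature_names_ = names
    model.n_labels_ = {cls: int(np.sum(y == cls)) for cls in model.classes_}
    model.train_accuracy_ = float(np.mean(forest.predict(X) == y))
    return model


def predict(model: PixelClassifier, img: Image) -> ProbabilityMap:
    """Probability map of one image under a trained model."""
    return model.predict_proba_map(img)


def batch_predict(model: PixelClassifier, images: list[Image]) -> list[ProbabilityMap]:
    """Probability maps for a list of images, order preserved.

    A failure on one image is re-raised with that image's identifier.
    """
    maps = []
    for image in images:
        try:
            maps.append(model.predict_proba_map(image))
        except NotFittedError:
            raise
        except Exception as exc:
            raise RuntimeError(
                f"prediction failed on image {image.identifier!r}: {exc}") from exc
    return maps
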