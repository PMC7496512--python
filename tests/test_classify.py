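"""Feature bank and random-forest pixel classification."""

import numpy as np
import pytest
from scipy import ndimage
from sklearn.exceptions import NotFittedError

from agglomsizer.classify import (
    PixelClassifier,
    batch_predict,
    compute_features,
    predict,
    train,
)
from agglomsizer.containers import (
    LABEL_AGGLOMERATE,
    LABEL_BACKGROUND,
    Image,
    ScribbleSet,
)


def _scribbles(fg_mask, n_per_class, seed, image_id="img"):
    rng = np.random.default_rng(seed)
    fg = np.argwhere(fg_mask)
    bg = np.argwhere(~fg_mask)
    fi = fg[rng.choice(len(fg), n_per_class, replace=False)]
    bi = bg[rng.choice(len(bg), n_per_class, replace=False)]
    rows = np.concatenate([fi[:, 0], bi[:, 0]])
    cols = np.concatenate([fi[:, 1], bi[:, 1]])
    labels = np.array([LABEL_AGGLOMERATE] * n_per_class
                      + [LABEL_BACKGROUND] * n_per_class, dtype=object)
    return ScribbleSet(rows, cols, labels, image_id)


def _separable_scene(seed=0, shape=(96, 96)):
    """Bright blobs (200) on dark background (50) with sigma-5 noise."""
    rng = np.random.default_rng(seed)
    fg = np.zeros(shape, dtype=bool)
    for r, c in [(20, 20), (60, 30), (40, 70), (75, 70)]:
        rr, cc = np.ogrid[:shape[0], :shape[1]]
        fg |= (rr - r) ** 2 + (cc - c) ** 2 <= 8**2
    pixels = np.where(fg, 200.0, 50.0) + 5.0 * rng.standard_normal(shape)
    return Image(np.clip(pixels, 0, None), 10.0, f"sep{seed}"), fg


class TestFeatures:
    def test_constant_image_derivative_features_zero(self):
        img = Image(np.full((48, 48), 321.0), 10.0, "c")
        stack = compute_features(img, (1.0, 3.5))
        for i, name in enumerate(stack.names):
            plane = stack.data[..., i]
            if name.startswith("intensity"):
                assert np.allclose(plane, 321.0, rtol=1e-9)
            else:
                assert np.max(np.abs(plane)) <= 1e-6 * 321.0, name

    def test_step_edge_gradient_peaks_on_edge(self):
        pixels = np.zeros((48, 48))
        pixels[:, 24:] = 100.0
        stack = compute_features(Image(pixels, 10.0, "step"), (1.0,))
        grad = stack.data[..., stack.names.index("gradmag_s1")]
        # oracle: finite-difference gradient of the sigma-1 smoothed image;
        # the edge sits between columns 23 and 24, both peaks land there
        sm = ndimage.gaussian_filter(pixels, 1.0)
        oracle = np.hypot(*np.gradient(sm))
        assert np.argmax(grad[24]) in (23, 24)
        assert np.argmax(oracle[24]) in (23, 24)
        edge_band = grad[:, 22:26]
        assert edge_band.max() == grad.max()
        assert grad[:, :16].max() < 0.05 * grad.max()

    def test_deterministic_and_validated(self):
        img, _ = _separable_scene()
        a = compute_features(img, (0.7, 1.6))
        b = compute_features(img, (0.7, 1.6))
        assert np.array_equal(a.data, b.data)
        with pytest.raises(ValueError, match="non-empty"):
            compute_features(img, ())
        with pytest.raises(ValueError, match="> 0"):
            compute_features(img, (0.0,))


class TestTraining:
    def test_separable_scene_heldout_accuracy(self):
        img, fg = _separable_scene(seed=1)
        scr = _scribbles(fg, 50, seed=2)
        model = train(img, scr, seed=0)
        # held out: every pixel, excluding a 2-px boundary band
        band = ndimage.binary_dilation(fg, iterations=2) & ~ndimage.binary_erosion(
            fg, iterations=2)
        pm = model.predict_proba_map(img)
        pred = pm.values >= 0.5
        ok = (pred == fg)[~band]
        assert ok.mean() >= 0.99
        assert model.train_accuracy_ >= 0.99

    def test_same_seed_identical_probability_maps(self):
        img, fg = _separable_scene(seed=3)
        scr = _scribbles(fg, 30, seed=4)
        m1 = train(img, scr, seed=9)
        m2 = train(img, scr, seed=9)
        assert np.array_equal(m1.predict_proba_map(img).values,
                              m2.predict_proba_map(img).values)

    def test_single_class_raises_naming_class(self):
        img, fg = _separable_scene()
        rc = np.argwhere(fg)[:20]
        scr = ScribbleSet(rc[:, 0], rc[:, 1],
                          np.array([LABEL_AGGLOMERATE] * 20, dtype=object), "img")
        with pytest.raises(ValueError, match="background"):
            train(img, scr)

    def test_out_of_bounds_scribble_raises(self):
        img, _ = _separable_scene()
        scr = ScribbleSet([5, 200], [5, 5],
                          np.array([LABEL_AGGLOMERATE, LABEL_BACKGROUND], dtype=object),
                          "img")
        with pytest.raises(ValueError, match="outside"):
            train(img, scr)

    def test_label_floor_enforced(self):
        img, fg = _separable_scene()
        scr = _scribbles(fg, 5, seed=0)
        with pytest.raises(ValueError, match="at least"):
            train(img, scr)

    def test_adding_correct_scribbles_does_not_hurt(self):
        # monotone improvement: more correct labels never cost >2% accuracy
        img, fg = _separable_scene(seed=5)
        band = ndimage.binary_dilation(fg, iterations=2) & ~ndimage.binary_erosion(
            fg, iterations=2)
        accs = []
        for n in (25, 100):
            model = train(img, _scribbles(fg, n, seed=6), seed=1)
            pred = model.predict_proba_map(img).values >= 0.5
            accs.append((pred == fg)[~band].mean())
        assert accs[1] >= accs[0] - 0.02


class TestPrediction:
    def test_training_pixels_recovered(self):
        img, fg = _separable_scene(seed=7)
        scr = _scribbles(fg, 50, seed=8)
        model = train(img, scr, seed=2)
        pm = predict(model, img)
        agg = scr.labels == LABEL_AGGLOMERATE
        assert (pm.values[scr.rows[agg], scr.cols[agg]] > 0.5).mean() >= 0.95

    def test_probabilities_normalized(self):
        img, fg = _separable_scene(seed=7)
        model = train(img, _scribbles(fg, 30, seed=8), seed=2)
        X = np.zeros((4, len(model.feature_names_)))
        assert np.allclose(model.forest_.predict_proba(X).sum(axis=1), 1.0)
        pm = model.predict_proba_map(img)
        assert pm.values.min() >= 0.0 and pm.values.max() <= 1.0

    def test_background_only_image_scores_low(self):
        img, fg = _separable_scene(seed=9)
        model = train(img, _scribbles(fg, 50, seed=1), seed=3)
        rng = np.random.default_rng(11)
        bg_img = Image(np.clip(50.0 + 5.0 * rng.standard_normal((96, 96)), 0, None),
                       10.0, "bg_only")
        assert model.predict_proba_map(bg_img).values.mean() < 0.5

    def test_untrained_model_raises(self):
        img, _ = _separable_scene()
        with pytest.raises(NotFittedError):
            PixelClassifier().predict_proba_map(img)


class TestBatch:
    def test_empty_and_order(self):
        img, fg = _separable_scene(seed=10)
        model = train(img, _scribbles(fg, 30, seed=0), seed=0)
        assert batch_predict(model, []) == []
        imgs = [Image(img.pixels + k, 10.0, f"im{k}") for k in range(3)]
        maps = batch_predict(model, imgs)
        assert [m.image_id for m in maps] == ["im0", "im1", "im2"]

    def test_failure_names_image(self):
        img, fg = _separable_scene(seed=10)
        model = train(img, _scribbles(fg, 30, seed=0), seed=0)

        class Broken:
            identifier = "corrupt_007"

            @property
            def pixels(self):
                raise OSError("truncated file")

        with pytest.raises(RuntimeError, match="corrupt_007"):
            batch_predict(model, [img, Broken()])


def test_model_round_trip(tmp_path):
    img, fg = _separable_scene(seed=12)
    model = train(img, _scribbles(fg, 30, seed=0), seed=4)
    path = tmp_path / "model.joblib"
    model.save(str(path))
    loaded = PixelClassifier.load(str(path))
    assert np.array_equal(loaded.predict_proba_map(img).values,
                          model.predict_proba_map(img).values)
    assert loaded.get_params() == model.get_params()
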