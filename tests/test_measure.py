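"""Object identification, halo erosion, Feret and shape descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy.spatial.distance import pdist

from agglomsizer.containers import Image, LabelMask, ProbabilityMap
from agglomsizer.measure import (
    erode_objects,
    feret_diameter,
    measure_all,
    segment,
    shape_descriptors,
)


def brute_force_feret(pixels, pixel_size=1.0):
    """O(n^2) oracle: max distance over ALL unit-square corner pairs."""
    rc = np.asarray(pixels, dtype=float).reshape(-1, 2)
    corners = np.concatenate([rc + off for off in
                              ([0, 0], [0, 1], [1, 0], [1, 1])])
    corners = np.unique(corners, axis=0)
    return pdist(corners).max() * pixel_size


def random_blob(rng, size=24):
    """Connected random pixel blob via dilated random walk."""
    canvas = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    for _ in range(rng.integers(3, 60)):
        canvas[r, c] = True
        r = int(np.clip(r + rng.integers(-1, 2), 0, size - 1))
        c = int(np.clip(c + rng.integers(-1, 2), 0, size - 1))
    if rng.random() < 0.5:
        canvas = ndimage.binary_dilation(canvas, iterations=int(rng.integers(1, 3)))
    return np.argwhere(canvas)


class TestSegment:
    def _pm(self, values):
        return ProbabilityMap(values, "t")

    def test_all_zero_map_empty_mask(self):
        mask = segment(self._pm(np.zeros((32, 32))))
        assert mask.n_objects == 0

    def test_single_block(self):
        v = np.zeros((32, 32))
        v[5:15, 5:15] = 1.0
        mask = segment(self._pm(v), threshold=0.5, min_size=4)
        assert mask.n_objects == 1
        assert (mask.labels == 1).sum() == 100

    def test_corner_touch_is_one_object_under_8_connectivity(self):
        v = np.zeros((32, 32))
        v[5:10, 5:10] = 1.0
        v[10:15, 10:15] = 1.0
        mask = segment(self._pm(v), min_size=1)
        assert mask.n_objects == 1
        # oracle: 4-connectivity would split it
        _, n4 = ndimage.label(v >= 0.5)
        assert n4 == 2

    def test_min_size_filters(self):
        v = np.zeros((32, 32))
        v[2, 2] = 1.0  # 1 px, below min_size 4
        v[10:12, 10:12] = 1.0  # 2x2, kept
        mask = segment(self._pm(v), min_size=4)
        assert mask.n_objects == 1

    def test_threshold_validated(self):
        with pytest.raises(ValueError, match="threshold"):
            segment(self._pm(np.zeros((8, 8))), threshold=0.0)


class TestErosion:
    def _mask_from(self, binary):
        lab, _ = ndimage.label(binary, structure=np.ones((3, 3)))
        return LabelMask(lab)

    def test_5x5_square_erodes_to_3x3(self):
        b = np.zeros((16, 16), bool)
        b[4:9, 4:9] = True
        out = erode_objects(self._mask_from(b), 1)
        expect = np.zeros((16, 16), bool)
        expect[5:8, 5:8] = True
        assert np.array_equal(out.labels > 0, expect)

    def test_2x2_object_dropped_and_logged(self):
        b = np.zeros((16, 16), bool)
        b[2:4, 2:4] = True
        b[8:13, 8:13] = True
        out = erode_objects(self._mask_from(b), 1)
        assert out.n_objects == 1
        assert len(out.dropped_ids) == 1

    def test_zero_iterations_identity(self):
        b = np.zeros((16, 16), bool)
        b[2:7, 3:11] = True
        mask = self._mask_from(b)
        out = erode_objects(mask, 0)
        assert np.array_equal(out.labels, mask.labels)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_erosion_monotone_in_area_and_feret(self, seed):
        rng = np.random.default_rng(seed)
        rc = random_blob(rng)
        b = np.zeros((24, 24), bool)
        b[rc[:, 0], rc[:, 1]] = True
        mask = self._mask_from(b)
        prev_area, prev_feret = None, None
        for n in range(3):
            out = erode_objects(mask, n)
            if out.n_objects == 0:
                break
            area = (out.labels > 0).sum()
            feret = feret_diameter(np.argwhere(out.labels > 0))
            if prev_area is not None:
                assert area <= prev_area
                assert feret <= prev_feret + 1e-9
            prev_area, prev_feret = area, feret


class TestFeret:
    def test_single_pixel_is_sqrt2(self):
        assert feret_diameter([(3, 4)], 1.0) == pytest.approx(np.sqrt(2))

    def test_3x4_rectangle_is_5(self):
        rc = [(r, c) for r in range(3) for c in range(4)]
        assert feret_diameter(rc, 1.0) == pytest.approx(5.0)

    def test_pixel_size_scales(self):
        rc = [(r, c) for r in range(3) for c in range(4)]
        assert feret_diameter(rc, 30.0) == pytest.approx(150.0)

    def test_matches_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            rc = random_blob(rng)
            assert feret_diameter(rc) == pytest.approx(brute_force_feret(rc), abs=0)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            feret_diameter([])


def disk_pixels(r, size=None):
    size = size or 2 * r + 5
    rr, cc = np.mgrid[:size, :size]
    m = (rr + 0.5 - size / 2) ** 2 + (cc + 0.5 - size / 2) ** 2 <= (r + 0.5) ** 2
    return np.argwhere(m)


class TestShape:
    def test_square_form_factor_approaches_pi_over_4(self):
        s = 100
        rc = [(r, c) for r in range(s) for c in range(s)]
        ff = shape_descriptors(rc)["form_factor"]
        assert ff == pytest.approx(np.pi / 4, abs=0.02)
        # convergence from above as s grows
        ff_small = shape_descriptors(
            [(r, c) for r in range(20) for c in range(20)])["form_factor"]
        assert ff_small > ff > np.pi / 4

    def test_disk_form_factor_near_one(self):
        ff = shape_descriptors(disk_pixels(20))["form_factor"]
        assert 0.9 <= ff <= 1.1

    def test_disk_axes_nearly_equal(self):
        d = shape_descriptors(disk_pixels(20))
        assert d["major_axis"] == pytest.approx(d["minor_axis"], rel=0.02)
        assert d["major_axis"] == pytest.approx(40, rel=0.06)

    def test_single_pixel_has_positive_axes(self):
        d = shape_descriptors([(0, 0)])
        assert d["minor_axis"] > 0
        assert d["form_factor"] > 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_shape_invariants_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        rc = random_blob(rng)
        d = shape_descriptors(rc)
        feret = feret_diameter(rc)
        assert d["minor_axis"] > 0
        assert d["major_axis"] >= d["minor_axis"]
        # isodiametric inequality: equivalent diameter never exceeds Feret
        assert d["equivalent_diameter"] <= feret + 1e-9
        assert d["area"] == len(rc)


class TestMeasureAll:
    def _img(self, shape=(32, 32), ps=10.0):
        return Image(np.zeros(shape), ps, "img")

    def test_empty_mask_empty_table(self):
        mask = LabelMask(np.zeros((32, 32), dtype=np.int32))
        table = measure_all(mask, self._img())
        assert len(table) == 0
        assert list(table.columns)[:3] == ["image_id", "object_id", "feret_nm"]

    def test_5x5_square_at_10nm(self):
        lab = np.zeros((32, 32), dtype=np.int32)
        lab[4:9, 4:9] = 1
        table = measure_all(LabelMask(lab), self._img())
        assert table.area_nm2.iloc[0] == pytest.approx(2500.0)
        assert table.feret_nm.iloc[0] == pytest.approx(np.sqrt(50) * 10)

    def test_scale_covariance(self):
        lab = np.zeros((32, 32), dtype=np.int32)
        lab[4:9, 4:12] = 1
        lab[20:26, 10:14] = 2
        t1 = measure_all(LabelMask(lab), self._img(ps=10.0))
        t2 = measure_all(LabelMask(lab), Image(np.zeros((32, 32)), 20.0, "img"))
        for col in ("feret_nm", "perimeter_nm", "major_nm", "minor_nm", "eqdiam_nm"):
            assert np.allclose(t2[col], 2 * t1[col])
        assert np.allclose(t2.area_nm2, 4 * t1.area_nm2)
        assert np.allclose(t2.form_factor, t1.form_factor)

    def test_shape_mismatch_raises(self):
        mask = LabelMask(np.zeros((16, 16), dtype=np.int32))
        with pytest.raises(ValueError, match="match"):
            measure_all(mask, self._img((32, 32)))
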