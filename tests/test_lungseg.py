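"""Lung segmentation stages: examples, oracles, morphology properties."""

import numpy as np
import pytest
from scipy import ndimage

from nodulescan import (
    BinaryMask,
    binarize_lung_candidates,
    fill_holes,
    iterative_mean_threshold,
    remove_border_connected,
    remove_trachea,
    segment_lungs,
    smooth_boundary,
)
from skimage import morphology

from conftest import make_slice


def border_floodfill_oracle(mask):
    """Brute-force oracle: flood fill from every border pixel, subtract."""
    m = mask.astype(bool)
    seen = np.zeros_like(m)
    stack = [
        (r, c)
        for r in range(m.shape[0])
        for c in range(m.shape[1])
        if (r in (0, m.shape[0] - 1) or c in (0, m.shape[1] - 1)) and m[r, c]
    ]
    while stack:
        r, c = stack.pop()
        if seen[r, c] or not m[r, c]:
            continue
        seen[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < m.shape[0] and 0 <= cc < m.shape[1]:
                    if m[rr, cc] and not seen[rr, cc]:
                        stack.append((rr, cc))
    return m & ~seen


def shift_dilate(mask, footprint):
    """Minkowski dilation by explicit shifts (outside = False)."""
    out = np.zeros_like(mask)
    cr, cc = np.array(footprint.shape) // 2
    for dr, dc in zip(*np.nonzero(footprint)):
        src = np.zeros_like(mask)
        r0, c0 = dr - cr, dc - cc
        rs = slice(max(0, r0), mask.shape[0] + min(0, r0))
        cs = slice(max(0, c0), mask.shape[1] + min(0, c0))
        rd = slice(max(0, -r0), mask.shape[0] + min(0, -r0))
        cd = slice(max(0, -c0), mask.shape[1] + min(0, -c0))
        src[rs, cs] = mask[rd, cd]
        out |= src
    return out


def shift_erode(mask, footprint):
    """Minkowski erosion by explicit shifts (outside = True)."""
    out = np.ones_like(mask)
    cr, cc = np.array(footprint.shape) // 2
    for dr, dc in zip(*np.nonzero(footprint)):
        src = np.ones_like(mask)
        r0, c0 = cr - dr, cc - dc  # reflected offset
        rs = slice(max(0, r0), mask.shape[0] + min(0, r0))
        cs = slice(max(0, c0), mask.shape[1] + min(0, c0))
        rd = slice(max(0, -r0), mask.shape[0] + min(0, -r0))
        cd = slice(max(0, -c0), mask.shape[1] + min(0, -c0))
        src[rs, cs] = mask[rd, cd]
        out &= src
    return out


class TestBinarize:
    def test_constant_above_threshold_all_false(self):
        m = binarize_lung_candidates(make_slice(np.full((6, 6), 10.0)), t=5.0)
        assert not m.pixels.any()

    def test_equal_to_threshold_included_dark_side(self):
        m = binarize_lung_candidates(make_slice(np.full((6, 6), 5.0)), t=5.0)
        assert m.pixels.all()

    def test_phantom_lungs_covered_before_border_removal(self, clean_phantom_slice):
        s, truth = clean_phantom_slice
        t = iterative_mean_threshold(s).t
        m = binarize_lung_candidates(s, t)
        filled = fill_holes(BinaryMask(m.pixels & truth.lung_mask.pixels, "lung"))
        inter = (filled.pixels & truth.lung_mask.pixels).sum()
        union = (filled.pixels | truth.lung_mask.pixels).sum()
        assert inter / union > 0.95


class TestRemoveBorderConnected:
    def test_single_component_touching_edge_removed(self):
        m = np.zeros((8, 8), bool)
        m[0:3, 2:5] = True
        out = remove_border_connected(BinaryMask(m, "lung"))
        assert not out.pixels.any()

    def test_interior_component_survives(self):
        m = np.zeros((8, 8), bool)
        m[0:2, 0:2] = True  # touches border
        m[4:6, 4:6] = True  # interior
        out = remove_border_connected(BinaryMask(m, "lung"))
        assert out.pixels.sum() == 4
        assert out.pixels[4:6, 4:6].all()

    def test_matches_border_floodfill_oracle_on_random_masks(self, rng):
        for _ in range(10):
            m = rng.random((64, 64)) < 0.45
            out = remove_border_connected(BinaryMask(m, "lung"))
            np.testing.assert_array_equal(out.pixels, border_floodfill_oracle(m))

    def test_idempotent(self, rng):
        m = BinaryMask(rng.random((40, 40)) < 0.4, "lung")
        once = remove_border_connected(m)
        twice = remove_border_connected(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)


class TestFillHoles:
    def test_punched_disk_refilled(self):
        m = np.zeros((20, 20), bool)
        rr, cc = np.ogrid[:20, :20]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 49
        m[disk] = True
        m[9:12, 9:12] = False
        out = fill_holes(BinaryMask(m, "lung"))
        np.testing.assert_array_equal(out.pixels, disk)

    def test_open_channel_not_filled(self):
        m = np.ones((10, 10), bool)
        m[0:6, 5] = False  # channel open to the top border
        out = fill_holes(BinaryMask(m, "lung"))
        np.testing.assert_array_equal(out.pixels, m)

    def test_superset_and_zero_holes(self, rng):
        for _ in range(10):
            m = rng.random((48, 48)) < 0.5
            out = fill_holes(BinaryMask(m, "lung"))
            assert (out.pixels | m).sum() == out.pixels.sum()  # superset
            # Euler-style oracle: background components minus the border one
            bg_labels, n_bg = ndimage.label(
                ~out.pixels, structure=ndimage.generate_binary_structure(2, 1)
            )
            border = set(np.unique(bg_labels[0, :])) | set(np.unique(bg_labels[-1, :]))
            border |= set(np.unique(bg_labels[:, 0])) | set(np.unique(bg_labels[:, -1]))
            interior_bg = set(range(1, n_bg + 1)) - border
            assert not interior_bg  # no closed holes remain
            # idempotent
            np.testing.assert_array_equal(fill_holes(out).pixels, out.pixels)


class TestRemoveTrachea:
    def test_third_smallest_blob_removed(self):
        m = np.zeros((40, 60), bool)
        m[5:25, 2:27] = True          # 500 px
        m[5:25, 33:57] = True         # 480 px
        m[30:35, 28:36] = True        # 40 px
        out = remove_trachea(BinaryMask(m, "lung"))
        labels, n = ndimage.label(out.pixels, structure=np.ones((3, 3), bool))
        assert n == 2
        assert not out.pixels[30:35, 28:36].any()

    def test_two_blobs_unchanged(self):
        m = np.zeros((20, 20), bool)
        m[2:8, 2:8] = True
        m[12:18, 12:18] = True
        out = remove_trachea(BinaryMask(m, "lung"))
        np.testing.assert_array_equal(out.pixels, m)


class TestSmoothBoundary:
    def test_solid_rectangle_unchanged(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        out = smooth_boundary(BinaryMask(m, "lung"), radius=2)
        np.testing.assert_array_equal(out.pixels, m)

    def test_narrow_slit_closed_at_radius_2(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        m[9, 5:8] = False  # 1-px-wide slit cut into the boundary
        out = smooth_boundary(BinaryMask(m, "lung"), radius=2)
        # the slit interior is sealed (the disk cannot enter a 1-px
        # channel); the mouth pixel stays open, reachable from outside
        assert out.pixels[9, 6] and out.pixels[9, 7]

    def test_matches_explicit_dilate_then_erode(self, rng):
        fp = morphology.disk(2)
        for _ in range(10):
            m = rng.random((40, 40)) < 0.5
            out = smooth_boundary(BinaryMask(m, "lung"), radius=2)
            oracle = shift_erode(shift_dilate(m, fp), fp)
            np.testing.assert_array_equal(out.pixels, oracle)

    def test_default_radius_is_2(self):
        import inspect

        assert inspect.signature(smooth_boundary).parameters["radius"].default == 2


class TestSegmentLungs:
    def test_phantom_lung_iou_above_0p9(self, phantom_slice):
        s, truth = phantom_slice
        t = iterative_mean_threshold(s).t
        m = segment_lungs(s, t)
        inter = (m.pixels & truth.lung_mask.pixels).sum()
        union = (m.pixels | truth.lung_mask.pixels).sum()
        assert inter / union > 0.9

    def test_two_components_on_phantom(self, phantom_slice):
        s, truth = phantom_slice
        t = iterative_mean_threshold(s).t
        m = segment_lungs(s, t)
        _, n = ndimage.label(m.pixels, structure=np.ones((3, 3), bool))
        assert n == 2

    def test_all_bright_slice_warns_and_returns_empty(self):
        s = make_slice(np.full((32, 32), 3000.0))
        with pytest.warns(UserWarning, match="no lung component"):
            m = segment_lungs(s, t=100.0)
        assert not m.pixels.any()

    def test_resmoothing_is_idempotent(self, phantom_slice):
        s, _ = phantom_slice
        t = iterative_mean_threshold(s).t
        m = segment_lungs(s, t)
        again = smooth_boundary(m, radius=2)
        np.testing.assert_array_equal(m.pixels, again.pixels)
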