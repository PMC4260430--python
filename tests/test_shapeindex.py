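"""Shape index: canonical classes, curvature oracles, component filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulescan import (
    BinaryMask,
    filter_by_shape_index,
    principal_curvatures,
    segment_candidates,
    shape_index_at,
    shape_index_map,
)

from conftest import make_slice


class TestCanonicalValues:
    @pytest.mark.parametrize(
        "k1,k2,expected",
        [
            (1.0, 1.0 - 1e-13, 0.00),   # cup: both positive, symmetric limit
            (1.0, 0.0, 0.25),           # rut: one zero, other concave-up
            (1.0, -1.0, 0.50),          # saddle
            (0.0, -1.0, 0.75),          # ridge: one zero, other convex-up
            (-1.0 + 1e-13, -1.0, 1.00), # cap: both negative, symmetric limit
        ],
    )
    def test_five_classes(self, k1, k2, expected):
        assert shape_index_at(k1, k2) == pytest.approx(expected, abs=1e-12)

    def test_exact_symmetric_limits(self):
        assert shape_index_at(2.0, 2.0) == 0.0    # cup limit
        assert shape_index_at(-2.0, -2.0) == 1.0  # cap limit
        assert np.isnan(shape_index_at(0.0, 0.0))


class TestFormulaProperties:
    @given(
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=0.1, max_value=100),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_scale_invariance_and_duality(self, k1, k2, c):
        if k1 == k2:
            return
        si = shape_index_at(k1, k2)
        assert 0.0 <= si <= 1.0
        assert shape_index_at(c * k1, c * k2) == pytest.approx(si, abs=1e-9)
        # cup/cap duality: (k1,k2) -> (-k2,-k1) maps SI -> 1 - SI
        assert shape_index_at(-k2, -k1) == pytest.approx(1.0 - si, abs=1e-9)


class TestPrincipalCurvatures:
    def test_plane_has_zero_curvature(self):
        rr, cc = np.meshgrid(np.arange(48.0), np.arange(48.0), indexing="ij")
        s = make_slice(0.3 * rr + 0.1 * cc)
        k1, k2 = principal_curvatures(s, sigma=1.5)
        # interior only: the replicated boundary bends the plane within
        # one kernel radius (12 px at sigma 1.5) of the edge
        assert np.abs(k1[14:-14, 14:-14]).max() < 1e-9
        assert np.abs(k2[14:-14, 14:-14]).max() < 1e-9

    @pytest.mark.parametrize("metric", ["hessian", "graph"])
    def test_quadratic_bowl_unit_curvature_at_apex(self, metric):
        n = 41
        rr, cc = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
        s = make_slice((rr.astype(float) ** 2 + cc.astype(float) ** 2) / 2.0)
        k1, k2 = principal_curvatures(s, sigma=1.5, metric=metric)
        c = n // 2
        # Gaussian smoothing of a quadratic preserves its Hessian up to
        # the discrete kernel's moment error; the gradient vanishes at
        # the apex so both metrics agree there.
        assert k1[c, c] == pytest.approx(1.0, abs=0.05)
        assert k2[c, c] == pytest.approx(1.0, abs=0.05)

    def test_saddle_antisymmetric_curvatures(self):
        n = 41
        rr, cc = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
        s = make_slice((cc.astype(float) ** 2 - rr.astype(float) ** 2) / 2.0)
        k1, k2 = principal_curvatures(s, sigma=1.5)
        c = n // 2
        assert k1[c, c] == pytest.approx(-k2[c, c], abs=1e-9)

    def test_ordering_k1_ge_k2(self, rng):
        s = make_slice(rng.uniform(0, 100, (24, 24)))
        k1, k2 = principal_curvatures(s, sigma=1.5)
        assert (k1 >= k2 - 1e-12).all()


class TestShapeIndexMap:
    def test_constant_image_all_undefined(self):
        m = shape_index_map(make_slice(np.full((16, 16), 5.0)), sigma=1.5)
        assert not m.defined.any()

    def test_bright_gaussian_blob_scores_cap(self):
        n = 41
        rr, cc = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
        blob = 1000.0 * np.exp(-(rr**2 + cc**2) / (2 * 6.0**2))
        m = shape_index_map(make_slice(blob), sigma=2.5)
        core = rr**2 + cc**2 <= 36
        assert np.nanmean(m.si[core]) > 0.76

    def test_bright_straight_tube_scores_ridge(self):
        n = 41
        rr, cc = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
        tube = 1000.0 * np.exp(-(rr**2) / (2 * 2.0**2))
        m = shape_index_map(make_slice(tube), sigma=2.5)
        core = (np.abs(rr) <= 1) & (np.abs(cc) <= 12)
        mean_si = np.nanmean(m.si[core])
        assert 0.6 <= mean_si <= 0.85


class TestFilter:
    def _candset(self, px, mask):
        return segment_candidates(make_slice(px), BinaryMask(mask, "final"))

    def test_boundary_mean_exactly_0p76_removed(self):
        # build a fake SI map with a known mean over one component
        px = np.zeros((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        cands = self._candset(px, mask)
        si = np.full((10, 10), np.nan)
        si[2:5, 2:5] = 0.76
        from nodulescan import ShapeIndexMap

        m = ShapeIndexMap(k1=np.zeros((10, 10)), k2=np.zeros((10, 10)), si=si, sigma=1.5)
        scored = filter_by_shape_index(cands, m)
        assert len(scored) == 1
        assert scored[0].mean_si == pytest.approx(0.76)
        assert not scored[0].is_nodule  # strictly greater than 0.76 required

    def test_all_undefined_component_removed_with_warning(self):
        px = np.zeros((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[2:6, 2:6] = True
        cands = self._candset(px, mask)
        from nodulescan import ShapeIndexMap

        m = ShapeIndexMap(
            k1=np.zeros((10, 10)), k2=np.zeros((10, 10)),
            si=np.full((10, 10), np.nan), sigma=1.5,
        )
        with pytest.warns(UserWarning, match="undefined"):
            scored = filter_by_shape_index(cands, m)
        assert scored[0].mean_si == 0.0
        assert not scored[0].is_nodule

    def test_threshold_monotone_in_retained_count(self, phantom_slice):
        from nodulescan.pipeline import PipelineConfig, run_slice

        s, _ = phantom_slice
        counts = []
        for thr in (0.5, 0.7, 0.76, 0.9):
            res = run_slice(s, PipelineConfig(si_threshold=thr))
            counts.append(len(res.retained))
        assert counts == sorted(counts, reverse=True)

    def test_phantom_nodule_retained_vessel_removed(self, phantom_slice):
        from nodulescan.pipeline import run_slice

        s, truth = phantom_slice
        res = run_slice(s)
        labs = res.candidates.labels
        retained = {sc.label for sc in res.retained}
        # the 12 mm isolated nodule's component is retained
        nod_labels = set(np.unique(labs[truth.nodule_mask == 1])) - {0}
        assert nod_labels & retained
        # no retained component is purely vascular
        for sc in res.retained:
            comp = labs == sc.label
            if (comp & truth.vessel_mask).any():
                assert (comp & (truth.nodule_mask > 0)).any()
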