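"""Histogram projection and fuzzy c-means middle-axis localisation.

The clustering is checked against an independently coded, loop-based
alternating-minimisation oracle sharing the same initialisation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnapose import BinaryMap, RunConfig, pressure_grid, thermal_grid
from somnapose.fcm_segment import (
    evenly_spaced_init,
    fcm_cluster,
    find_leg_middle_axis,
    find_middle_axis,
    find_trunk_middle_point,
    project_histogram,
    Projection,
)


def fcm_oracle(points, c, m, epsilon, max_iter, init):
    """Naive per-element alternating minimisation; returns final objective."""
    points = [tuple(p) for p in points]
    centers = [tuple(ck) for ck in init]
    n = len(points)

    def dist2(p, q):
        return (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2

    def memberships(centers):
        U = []
        for p in points:
            d2 = [dist2(p, ck) for ck in centers]
            if any(d == 0.0 for d in d2):
                hits = [1.0 if d == 0.0 else 0.0 for d in d2]
                U.append([h / sum(hits) for h in hits])
            else:
                row = []
                for k in range(c):
                    s = sum((d2[k] / d2[l]) ** (1.0 / (m - 1.0)) for l in range(c))
                    row.append(1.0 / s)
                U.append(row)
        return U

    U = memberships(centers)
    prev = float("inf")
    A = prev
    for _ in range(max_iter):
        new_centers = []
        for k in range(c):
            wsum = sum(U[i][k] ** m for i in range(n))
            px = sum(U[i][k] ** m * points[i][0] for i in range(n)) / wsum
            py = sum(U[i][k] ** m * points[i][1] for i in range(n)) / wsum
            new_centers.append((px, py))
        centers = new_centers
        A = sum(
            U[i][k] ** m * dist2(points[i], centers[k])
            for i in range(n)
            for k in range(c)
        )
        if abs(prev - A) < epsilon:
            break
        prev = A
        U = memberships(centers)
    return A, centers


def random_points(rng, n):
    pos = rng.choice(np.arange(16), size=n, replace=False).astype(float)
    counts = rng.integers(1, 12, size=n).astype(float)
    return np.column_stack([np.sort(pos), counts])


class TestProjection:
    def test_all_zero_map(self):
        bm = BinaryMap(grid=pressure_grid(), cells=np.zeros((16, 10), dtype=int))
        assert np.all(project_histogram(bm, "horizontal").counts == 0)

    def test_single_sensed_point(self):
        cells = np.zeros((16, 10), dtype=int)
        cells[3, 7] = 1
        bm = BinaryMap(grid=pressure_grid(), cells=cells)
        h = project_histogram(bm, "horizontal").counts
        v = project_histogram(bm, "vertical").counts
        assert h[7] == 1 and h.sum() == 1
        assert v[3] == 1 and v.sum() == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_counts_conserve_popcount(self, seed):
        cells = np.random.default_rng(seed).integers(0, 2, (16, 10))
        bm = BinaryMap(grid=pressure_grid(), cells=cells)
        for axis in ("horizontal", "vertical"):
            assert project_histogram(bm, axis).counts.sum() == bm.total

    def test_unknown_axis(self):
        bm = BinaryMap(grid=thermal_grid(), cells=np.zeros((8, 8), dtype=int))
        with pytest.raises(ValueError):
            project_histogram(bm, "diagonal")


class TestFCMCluster:
    def test_single_cluster_closed_form(self, rng):
        pts = random_points(rng, 6)
        res = fcm_cluster(pts, c=1)
        np.testing.assert_allclose(res.centers[0], pts.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(res.U, 1.0, atol=1e-12)

    def test_two_tight_groups_recover_group_means(self):
        a = np.array([[1.0, 5.0], [2.0, 5.2], [1.5, 4.8]])
        b = np.array([[11.0, 1.0], [12.0, 1.2], [11.5, 0.8]])
        pts = np.vstack([a, b])
        res = fcm_cluster(pts, c=2, epsilon=1e-10)
        got = res.centers[np.argsort(res.centers[:, 0])]
        np.testing.assert_allclose(got[0], a.mean(axis=0), atol=1e-3)
        np.testing.assert_allclose(got[1], b.mean(axis=0), atol=1e-3)
        assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_equidistant_point_splits_membership(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 0.0]])
        init = np.array([[0.0, 0.0], [10.0, 0.0]])
        res = fcm_cluster(pts, c=2, m=2.0, init=init)
        np.testing.assert_allclose(res.U[2], [0.5, 0.5], atol=1e-9)

    def test_point_on_center_gets_crisp_membership(self):
        pts = np.array([[0.0, 0.0], [4.0, 2.0], [9.0, 5.0]])
        init = np.array([[0.0, 0.0], [9.0, 5.0]])
        res = fcm_cluster(pts, c=2, init=init)
        row = res.membership_trace[0][0]
        np.testing.assert_allclose(row, [1.0, 0.0], atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 12), c=st.integers(1, 3))
    def test_matches_bruteforce_oracle(self, seed, n, c):
        pts = random_points(np.random.default_rng(seed), n)
        init = evenly_spaced_init(pts, c)
        res = fcm_cluster(pts, c=c, epsilon=1e-8, init=init)
        A_oracle, _ = fcm_oracle(pts, c, 2.0, 1e-8, 200, init)
        assert res.objective_trace[-1] == pytest.approx(A_oracle, abs=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 14))
    def test_memberships_normalised_every_iteration(self, seed, n):
        pts = random_points(np.random.default_rng(seed), n)
        res = fcm_cluster(pts, c=3)
        for U in res.membership_trace:
            np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((U >= 0) & (U <= 1))
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_validation(self):
        pts = np.array([[0.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError):
            fcm_cluster(pts, c=3)
        with pytest.raises(ValueError):
            fcm_cluster(pts, c=1, m=1.0)
        with pytest.raises(ValueError):
            fcm_cluster(pts, c=1, epsilon=0.0)


class TestMiddleAxis:
    def test_symmetric_unimodal_projection(self, cfg):
        counts = np.array([0, 1, 3, 6, 9, 9, 9, 6, 3, 1, 0])
        axis, _ = find_middle_axis(Projection("horizontal", counts), cfg)
        assert axis == 5

    def test_degenerate_two_cluster_tie_breaks_low(self, cfg):
        # two occupied indexes with equal mass: the documented tie rule
        # picks the cluster at the lower centre position
        counts = np.array([0, 5, 0, 0, 5, 0])
        axis, _ = find_middle_axis(Projection("horizontal", counts), cfg)
        assert axis == 1

    def test_no_sensed_points_is_degenerate(self, cfg):
        with pytest.raises(ValueError, match="degenerate"):
            find_middle_axis(Projection("horizontal", np.zeros(10, dtype=int)), cfg)

    def test_single_occupied_column_is_the_axis(self, cfg):
        cells = np.zeros((8, 8), dtype=int)
        cells[1:6, 5] = 1
        axis, _ = find_leg_middle_axis(BinaryMap(grid=thermal_grid(), cells=cells), cfg)
        assert axis == 5

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mirror_equivariance_exact(self, seed, cfg):
        rng = np.random.default_rng(seed)
        cells = (rng.random((16, 10)) < 0.35).astype(int)
        if cells.sum() < 3:
            cells[2:6, 3:6] = 1
        bm = BinaryMap(grid=pressure_grid(), cells=cells)
        axis, _ = find_middle_axis(project_histogram(bm, "horizontal"), cfg)
        maxis, _ = find_middle_axis(
            project_histogram(bm.mirrored(), "horizontal"), cfg
        )
        assert maxis == bm.grid.cols - 1 - axis


class TestTrunkMiddlePoint:
    def test_cross_point_assembles_axes(self, cfg, zero_noise_recordings):
        from somnapose.preprocess import preprocess_recording
        from somnapose.classify import SleepPosture

        p_seq, t_seq, truth = zero_noise_recordings[SleepPosture.SUPINE]
        pm, _ = preprocess_recording(p_seq, t_seq, cfg)
        axes = find_trunk_middle_point(pm, cfg)
        assert axes.cross_point == (axes.vertical_axis, axes.horizontal_axis)
        assert axes.cross_point == truth.cross_point

    def test_translation_equivariance(self, cfg, zero_noise_recordings):
        from somnapose.preprocess import preprocess_recording
        from somnapose.classify import SleepPosture

        p_seq, t_seq, _ = zero_noise_recordings[SleepPosture.SUPINE]
        pm, _ = preprocess_recording(p_seq, t_seq, cfg)
        shifted = np.roll(pm.cells, 1, axis=1)
        axes = find_trunk_middle_point(pm, cfg)
        axes_shifted = find_trunk_middle_point(
            BinaryMap(grid=pm.grid, cells=shifted), cfg
        )
        assert axes_shifted.horizontal_axis == axes.horizontal_axis + 1
        assert axes_shifted.vertical_axis == axes.vertical_axis
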