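from itertools import permutations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import ieegloc as il
from ieegloc.numbering import (assign_indices, build_ideal_grid, fit_sphere,
                               hull_corners, permute_refine, project_pca2,
                               radial_project)
from ieegloc.phantom import grid_cap_coordinates

from conftest import matches_truth_up_to_symmetry


def _es(L, kind="depth", rows=1, cols=None, pitch=10.0, indices=None):
    cols = cols if cols is not None else len(L)
    spec = il.ElectrodeArraySpec(kind, rows, cols, pitch, "E")
    return il.ElectrodeSet(L=np.asarray(L, dtype=float), spec=spec,
                           indices=indices)


class TestNumberDepth:
    def test_collinear_points_ordered_from_deep_end(self):
        L = np.array([(x, 0.0, 0.0) for x in range(0, 50, 5)])
        es = il.number_depth(_es(L), deep_end=(0, 0, 0))
        np.testing.assert_array_equal(es.indices, np.arange(1, 11))
        es2 = il.number_depth(_es(L), deep_end=(60, 0, 0))
        np.testing.assert_array_equal(es2.indices, np.arange(10, 0, -1))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        L = np.array([(x, 0.0, 0.0) for x in range(0, 50, 5)])
        perm = rng.permutation(10)
        a = il.number_depth(_es(L), deep_end=(0, 0, 0))
        b = il.number_depth(_es(L[perm]), deep_end=(0, 0, 0))
        # same index-to-coordinate mapping
        np.testing.assert_allclose(a.ordered(), b.ordered())

    def test_jittered_ordering_matches_true_axis_sort(self):
        rng = np.random.default_rng(1)
        axis = np.array([1.0, 2.0, -0.5])
        axis /= np.linalg.norm(axis)
        t = np.arange(8) * 10.0
        L = np.outer(t, axis) + rng.normal(0, 0.3, (8, 3))
        es = il.number_depth(_es(L), deep_end=L[0])
        np.testing.assert_array_equal(np.argsort(es.indices), np.argsort(t))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            il.number_depth(_es(np.zeros((4, 3))), deep_end=(0, 0, 0))

    def test_bounded_jitter_below_half_pitch_never_reorders(self):
        """Contacts displaced by less than pitch/2 keep their ordinal
        position along the array axis (100% recovery regime)."""
        rng = np.random.default_rng(2)
        pitch = 5.0
        t = np.arange(10) * pitch
        for _ in range(50):
            u = rng.normal(size=(10, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            mag = rng.uniform(0, 0.49 * pitch, size=(10, 1))
            L = np.column_stack([t, np.zeros(10), np.zeros(10)]) + u * mag
            es = il.number_depth(_es(L, pitch=pitch), deep_end=(0, 0, 0))
            np.testing.assert_array_equal(es.indices, np.arange(1, 11))


class TestProjectPCA2:
    def test_planar_grid_recovers_rigid_2d_geometry(self):
        spec = il.ElectrodeArraySpec("grid", 3, 4, 10.0, "G")
        L = grid_cap_coordinates(spec, il.GridPlacement(radius=None,
                                                        pole=(1, 1, 1)))
        p2 = project_pca2(L)
        d3 = np.linalg.norm(L[:, None] - L[None], axis=2)
        d2 = np.linalg.norm(p2[:, None] - p2[None], axis=2)
        np.testing.assert_allclose(d2, d3, atol=1e-9)

    def test_shallow_cap_preserves_chord_distances_within_5pct(self):
        spec = il.ElectrodeArraySpec("grid", 4, 5, 10.0, "G")
        L = grid_cap_coordinates(spec, il.GridPlacement(radius=80.0))
        p2 = project_pca2(L)
        d3 = np.linalg.norm(L[:, None] - L[None], axis=2)
        d2 = np.linalg.norm(p2[:, None] - p2[None], axis=2)
        mask = d3 > 0
        assert np.all(np.abs(d2[mask] - d3[mask]) / d3[mask] < 0.05)

    def test_collinear_rejected(self):
        L = np.outer(np.arange(5), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            project_pca2(L)


class TestHullCorners:
    def test_rectangle_corners_and_angles(self):
        spec = il.ElectrodeArraySpec("grid", 4, 5, 10.0, "G")
        L = grid_cap_coordinates(spec, il.GridPlacement(radius=None))
        p2 = project_pca2(L)
        outline, corners = hull_corners(p2)
        ext = {0, 4, 15, 19}           # row-major corner positions of 4x5
        assert set(corners) == ext
        top4 = np.sort(outline.transition_angles)[-4:]
        np.testing.assert_allclose(top4, 90.0, atol=1e-6)
        others = np.sort(outline.transition_angles)[:-4]
        np.testing.assert_allclose(others, 0.0, atol=1e-6)
        # convex polygon: exterior turns sum to 360 degrees
        assert outline.transition_angles.sum() == pytest.approx(360.0)

    def test_edge_midpoint_never_selected_as_corner(self):
        # midpoint pushed a hair off the edge so it stays a hull vertex
        square = np.array([(0, 0), (10, 0), (10, 10), (0, 10),
                           (5, -1e-6)], dtype=float)
        outline, corners = hull_corners(square)
        assert 4 not in corners
        mid_angle = outline.transition_angles[list(outline.vertex_ids).index(4)]
        assert mid_angle < 1e-3   # brute-force turn at a near-collinear vertex


class TestIdealGrid:
    def test_2x2_returns_corners(self):
        corners = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)],
                           dtype=float)
        ig = build_ideal_grid(corners, 2, 2)
        np.testing.assert_allclose(
            ig.flat(), [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])

    def test_2x3_includes_edge_midpoints(self):
        corners = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)],
                           dtype=float)
        ig = build_ideal_grid(corners, 2, 3)
        flat = ig.flat()
        assert any(np.allclose(p, (0.5, 0, 0)) for p in flat)
        assert any(np.allclose(p, (0.5, 1, 0)) for p in flat)

    def test_skewed_3x3_center_is_corner_mean(self):
        corners = np.array([(0, 0, 0), (4, 1, 0), (5, 6, 2), (-1, 5, 1)],
                           dtype=float)
        ig = build_ideal_grid(corners, 3, 3)
        np.testing.assert_allclose(ig.coords[1, 1], corners.mean(axis=0))


class TestSphereFit:
    def test_exact_recovery(self):
        rng = np.random.default_rng(3)
        center, radius = np.array([10.0, -5.0, 3.0]), 80.0
        u = rng.normal(size=(20, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        sf = fit_sphere(center + radius * u)
        assert not sf.is_planar
        np.testing.assert_allclose(sf.center, center, atol=1e-6)
        assert sf.radius == pytest.approx(radius, abs=1e-6)

    def test_coplanar_grid_engages_planar_fallback(self):
        spec = il.ElectrodeArraySpec("grid", 4, 4, 10.0, "G")
        L = grid_cap_coordinates(spec, il.GridPlacement(radius=None))
        sf = fit_sphere(L)
        assert sf.is_planar

    def test_jittered_radius_recovery_monte_carlo(self):
        """Radius estimate stays within 3*sigma/sqrt(K) of truth for the
        bulk of 100 jittered spherical caps (sigma = 0.5 mm, K = 20)."""
        sigma, radius, K = 0.5, 80.0, 20
        tol = 3 * sigma / np.sqrt(K)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            u = rng.normal(size=(K, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            sf = fit_sphere(radius * u + rng.normal(0, sigma, (K, 3)))
            if not sf.is_planar and abs(sf.radius - radius) <= tol:
                hits += 1
        assert hits >= 90


class TestRadialProject:
    def test_fixed_point_scaling_and_radius(self):
        sf = fit_sphere(np.array([(80., 0, 0), (-80., 0, 0), (0, 80., 0),
                                  (0, -80., 0), (0, 0, 80.)]))
        corners = np.array([(40., 0, 0), (0, 40., 0), (0, 40., 40.),
                            (40., 0, 40.)])
        ig = build_ideal_grid(corners, 2, 2)
        out = radial_project(ig, sf).reshape(-1, 3)
        np.testing.assert_allclose(np.linalg.norm(out - sf.center, axis=1),
                                   sf.radius, atol=1e-9)
        # a point already on the sphere stays put; half-radius scales out
        on = build_ideal_grid(np.array([(80., 0, 0)] * 4), 2, 2)
        on.coords[:] = np.array([80.0, 0, 0])
        np.testing.assert_allclose(
            radial_project(on, sf).reshape(-1, 3),
            np.tile([80.0, 0, 0], (4, 1)), atol=1e-9)


class TestAssignIndices:
    def test_identity_and_zero_distance_pairs_first(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3)) * 10
        np.testing.assert_array_equal(assign_indices(pts, pts),
                                      np.arange(1, 7))
        swapped = pts.copy()[[1, 0, 2, 3, 4, 5]]
        mapping = assign_indices(swapped, pts)
        np.testing.assert_array_equal(mapping, [2, 1, 3, 4, 5, 6])

    def test_greedy_matches_hungarian_on_jittered_grids(self):
        spec = il.ElectrodeArraySpec("grid", 2, 3, 10.0, "G")
        ideal = grid_cap_coordinates(spec, il.GridPlacement(radius=None))
        agree = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            real = ideal + rng.normal(0, 0.2 * 10.0, ideal.shape)
            mapping = assign_indices(real, ideal)
            d = np.linalg.norm(real[:, None] - ideal[None], axis=2)
            r, c = linear_sum_assignment(d)
            if np.array_equal(mapping[r] - 1, c):
                agree += 1
        assert agree >= 95


class TestPermuteRefine:
    def _setup(self, seed, jitter=0.5):
        spec = il.ElectrodeArraySpec("grid", 2, 3, 10.0, "G")
        ideal = grid_cap_coordinates(spec, il.GridPlacement(radius=None))
        rng = np.random.default_rng(seed)
        real = ideal + rng.normal(0, jitter, ideal.shape)
        return spec, real, ideal

    def test_optimal_mapping_is_fixed_point(self):
        spec, real, ideal = self._setup(0, jitter=0.1)
        mapping = np.arange(1, 7)
        out = permute_refine(mapping.copy(), real, ideal, spec)
        np.testing.assert_array_equal(out, mapping)

    def test_adjacent_swap_is_undone_and_global_optimum_reached(self):
        """On 2x3 grids the refined mapping attains the minimum real-ideal
        distance sum over all 720 permutations (exhaustive oracle)."""
        for seed in range(5):
            spec, real, ideal = self._setup(seed, jitter=0.5)
            best = min(
                sum(np.linalg.norm(real[i] - ideal[p[i]]) for i in range(6))
                for p in permutations(range(6)))
            start = np.array([2, 1, 3, 4, 5, 6])  # adjacent pair swapped
            out = permute_refine(start, real, ideal, spec)
            got = np.linalg.norm(real - ideal[out - 1], axis=1).sum()
            assert got == pytest.approx(best, abs=1e-9)


class TestFlipRotate:
    def _grid(self, rows, cols):
        spec = il.ElectrodeArraySpec("grid", rows, cols, 10.0, "G")
        L = grid_cap_coordinates(spec, il.GridPlacement(radius=None))
        return il.ElectrodeSet(L=L, spec=spec,
                               indices=np.arange(1, rows * cols + 1))

    def test_involutions_and_full_rotation(self):
        es = self._grid(2, 4)
        twice = il.flip_rotate(il.flip_rotate(es, "flip_lr"), "flip_lr")
        np.testing.assert_array_equal(twice.indices, es.indices)
        four = es
        for _ in range(4):
            four = il.flip_rotate(four, "rot_cw")
        np.testing.assert_array_equal(four.indices, es.indices)
        assert four.spec.rows == 2 and four.spec.cols == 4

    def test_rot_cw_on_2x4_swaps_spec_and_maps_lattice(self):
        es = self._grid(2, 4)
        out = il.flip_rotate(es, "rot_cw")
        assert (out.spec.rows, out.spec.cols) == (4, 2)
        cols_new = 2
        for old_i, new_i in zip(es.indices, out.indices):
            r, c = divmod(old_i - 1, 4)
            r2, c2 = c, 2 - 1 - r          # 90 degrees clockwise
            assert new_i == r2 * cols_new + c2 + 1


class TestNaming:
    def test_prefix_concatenation(self):
        es = _es(np.arange(9, dtype=float).reshape(3, 3),
                 indices=np.array([2, 1, 3]))
        named = il.name_electrodes(es, "Grid")
        assert named.names == ["Grid2", "Grid1", "Grid3"]
        assert sorted(named.names) == ["Grid1", "Grid2", "Grid3"]

    def test_explicit_list_by_index_and_length_check(self):
        es = _es(np.arange(9, dtype=float).reshape(3, 3),
                 indices=np.array([2, 1, 3]))
        named = il.name_electrodes(es, ["A", "B", "C"])
        assert named.names == ["B", "A", "C"]
        with pytest.raises(ValueError, match="expected 3"):
            il.name_electrodes(es, ["A", "B"])


class TestGridPipeline:
    @pytest.mark.parametrize("rows,cols", [(2, 4), (4, 5), (8, 8)])
    @pytest.mark.parametrize("radius", [None, 70.0, 90.0])
    def test_noiseless_recovery_up_to_lattice_symmetry(self, rows, cols,
                                                       radius):
        spec = il.ElectrodeArraySpec("grid", rows, cols, 10.0, "G")
        truth = grid_cap_coordinates(
            spec, il.GridPlacement(radius=radius, pole=(0.2, -0.1, 1.0),
                                   rotation_deg=23.0))
        rng = np.random.default_rng(rows * 100 + cols)
        es = il.ElectrodeSet(L=truth[rng.permutation(len(truth))], spec=spec)
        numbered = il.numbering.number_grid(es)
        assert matches_truth_up_to_symmetry(numbered, truth, rows)

    def test_pipeline_invariant_to_input_row_order(self):
        spec = il.ElectrodeArraySpec("grid", 4, 5, 10.0, "G")
        truth = grid_cap_coordinates(spec, il.GridPlacement(radius=80.0))
        rng = np.random.default_rng(9)
        maps = []
        for _ in range(3):
            perm = rng.permutation(len(truth))
            out = il.numbering.number_grid(
                il.ElectrodeSet(L=truth[perm], spec=spec))
            by_index = {i: tuple(np.round(xyz, 9))
                        for i, xyz in zip(out.indices, out.L)}
            maps.append(by_index)
        assert maps[0] == maps[1] == maps[2]
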