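import numpy as np
import pytest

import sfrtplan as sp
from sfrtplan.lattice import diameter_for_depth

from conftest import sphere_of_volume
from oracles import naive_greedy_placement


class TestTechniqueSelection:
    def test_large_target_gets_lattice(self, small_grid):
        assert sp.select_technique(sphere_of_volume(small_grid, 16.5)) == "LATTICE"

    def test_small_target_gets_scart(self, small_grid):
        assert sp.select_technique(sphere_of_volume(small_grid, 10.6)) == "SCART"

    def test_sub_threshold_target_excluded(self, small_grid):
        with pytest.raises(sp.TargetTooSmallError):
            sp.select_technique(sphere_of_volume(small_grid, 2.9))


class TestPlacement:
    def test_sphere_fits_single_central_vertex(self):
        # any second center would need 4 mm depth (within 16 mm of the
        # centroid) yet sit >= 25 mm from the central seed: impossible
        grid = sp.VoxelGrid.centered((24, 24, 24))
        gtv = sp.sphere_mask(grid, (0, 0, 0), 20.0, "GTV")
        lat = sp.place_vertices(gtv)
        assert lat.n_vertices == 1
        assert lat.vertices[0].center == (0.0, 0.0, 0.0)
        assert lat.vertices[0].diameter == 8.0

    def test_tiny_sphere_infeasible(self, small_grid):
        gtv = sp.sphere_mask(small_grid, (0, 0, 0), 3.0, "GTV")
        lat = sp.place_vertices(gtv)
        assert lat.n_vertices == 0 and lat.warnings

    def test_long_ellipsoid_takes_three_axis_vertices(self):
        grid = sp.VoxelGrid.centered((45, 25, 25))
        gtv = sp.ellipsoid_mask(grid, (0, 0, 0), (40, 20, 20), "GTV")
        lat = sp.place_vertices(gtv)
        centers = sorted(v.center for v in lat.vertices)
        assert lat.n_vertices == 3
        assert all(c[1] == 0.0 and c[2] == 0.0 for c in centers)

    def test_determinism(self):
        grid = sp.VoxelGrid.centered((45, 25, 25))
        gtv = sp.ellipsoid_mask(grid, (0, 0, 0), (40, 20, 20), "GTV")
        a = sp.place_vertices(gtv)
        b = sp.place_vertices(gtv)
        assert [(v.center, v.diameter) for v in a.vertices] == \
               [(v.center, v.diameter) for v in b.vertices]

    @pytest.mark.parametrize("shape,seed", [("ellipsoid", 1), ("strip", 2), ("star", 3)])
    def test_matches_exhaustive_candidate_scan(self, shape, seed):
        ph = sp.make_phantom(sp.PhantomSpec(gtv_shape=shape, gtv_scale=25.0,
                                            spacing=(2.0, 2.0, 2.0), seed=seed))
        gtv = ph["GTV"]
        cfg = sp.LatticePlacementConfig()
        lat = sp.place_vertices(gtv, cfg)
        expected = naive_greedy_placement(gtv, cfg, cfg.spacing_initial)
        assert [tuple(np.round(v.center, 6)) for v in lat.vertices] == \
               [tuple(np.round(c, 6)) for c in expected]

    def test_pairwise_spacing_invariant(self):
        ph = sp.make_phantom(sp.PhantomSpec(gtv_shape="star", gtv_scale=60.0, seed=11))
        cfg = sp.LatticePlacementConfig(spacing_initial=20.0)
        lat = sp.place_vertices(ph["GTV"], cfg)
        centers = np.array([v.center for v in lat.vertices])
        assert len(centers) >= 2
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.spacing_min

    def test_oar_clearance_invariant(self):
        grid = sp.VoxelGrid.centered((45, 25, 25))
        gtv = sp.ellipsoid_mask(grid, (0, 0, 0), (40, 20, 20), "GTV")
        oar = sp.sphere_mask(grid, (40, 0, 0), 6.0, "brainstem")
        cfg = sp.LatticePlacementConfig()
        lat = sp.place_vertices(gtv, cfg, oars=[oar])
        lat = sp.expand_vertices(lat, gtv, cfg, oars=[oar])
        sep = sp.min_surface_separation(lat.vtv_mask, oar)
        assert sep >= cfg.oar_clearance - max(grid.spacing)


class TestExpansion:
    def test_deep_center_caps_at_15mm(self):
        grid = sp.VoxelGrid.centered((24, 24, 24))
        gtv = sp.sphere_mask(grid, (0, 0, 0), 20.0, "GTV")
        lat = sp.expand_vertices(sp.place_vertices(gtv), gtv)
        assert lat.vertices[0].diameter == 15.0

    def test_diameter_rule_hand_values(self):
        cfg = sp.LatticePlacementConfig()
        assert diameter_for_depth(4.4, cfg) == 8.0    # floor: whole-mm, min 8
        assert diameter_for_depth(7.0, cfg) == 14.0
        assert diameter_for_depth(20.0, cfg) == 15.0  # cap

    def test_spheres_contained_in_gtv(self):
        ph = sp.make_phantom(sp.PhantomSpec(gtv_shape="star", gtv_scale=45.0, seed=5))
        gtv = ph["GTV"]
        lat = sp.expand_vertices(sp.place_vertices(gtv), gtv)
        assert lat.n_vertices >= 1
        assert not (lat.vtv_mask.data & ~gtv.data).any()

    def test_vgr_cap_respected(self):
        ph = sp.make_phantom(sp.PhantomSpec(gtv_shape="ellipsoid", gtv_scale=20.0, seed=2))
        gtv = ph["GTV"]
        cfg = sp.LatticePlacementConfig()
        lat = sp.expand_vertices(sp.place_vertices(gtv, cfg), gtv, cfg)
        voxel_cc = gtv.grid.voxel_volume_mm3 / 1000.0
        assert lat.vtv_mask.volume_cc <= cfg.vgr_cap * gtv.volume_cc + voxel_cc

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            sp.LatticePlacementConfig(spacing_min=10.0)  # below diameter_max


class TestCrop:
    def test_contained_vtv_unchanged(self):
        grid = sp.VoxelGrid.centered((24, 24, 24))
        gtv = sp.sphere_mask(grid, (0, 0, 0), 20.0, "GTV")
        lat = sp.place_vertices(gtv)
        cropped = sp.crop_vtv(lat, gtv)
        assert np.array_equal(cropped.vtv_mask.data, lat.vtv_mask.data)
        assert cropped.containment == "GTV_2mm"
        assert not any(v.clipped for v in cropped.vertices)

    def test_protruding_vertex_is_clipped(self):
        grid = sp.VoxelGrid.centered((24, 24, 24))
        gtv = sp.sphere_mask(grid, (0, 0, 0), 10.0, "GTV")
        vertex = sp.Vertex(center=(8.0, 0.0, 0.0), diameter=14.0)  # protrudes 5 mm
        from sfrtplan.lattice import rasterize_vtv
        lat = sp.LatticeVTV([vertex], rasterize_vtv(grid, [vertex]))
        cropped = sp.crop_vtv(lat, gtv)
        assert cropped.vtv_mask.volume_cc < lat.vtv_mask.volume_cc
        assert cropped.vertices[0].clipped
        region = sp.expand(gtv, 2.0)
        assert not (cropped.vtv_mask.data & ~region.data).any()

    def test_empty_lattice_passthrough(self, small_grid):
        gtv = sp.sphere_mask(small_grid, (0, 0, 0), 10.0, "GTV")
        empty = sp.LatticeVTV([], sp.StructureMask(small_grid, "VTV",
                                                   np.zeros(small_grid.shape, bool)))
        assert sp.crop_vtv(empty, gtv).containment == "GTV_2mm"


class TestTuning:
    def _gtv(self):
        grid = sp.VoxelGrid.centered((45, 25, 25))
        return sp.ellipsoid_mask(grid, (0, 0, 0), (40, 20, 20), "GTV")

    def test_early_exit_when_goal_met(self):
        calls = []

        def evaluator(lat):
            calls.append(lat.n_vertices)
            return 0.05

        lat = sp.tune_lattice(self._gtv(), evaluator=evaluator)
        assert lat.goal_met and len(calls) == 1
        assert len(lat.tuning_trace) == 1

    def test_exhaustion_returns_best_effort_with_flag(self):
        lat = sp.tune_lattice(self._gtv(), evaluator=lambda lat: 0.5)
        assert lat.goal_met is False and lat.warnings
        assert len(lat.tuning_trace) == 7  # 25..40 mm in 2.5 mm steps

    def test_monotone_evaluator_returns_minimal_passing_spacing(self):
        # ring V5Gy falling with spacing: first passing spacing is returned
        def evaluator(lat):
            centers = np.array([v.center for v in lat.vertices])
            if len(centers) < 2:
                return 0.0
            d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            spacing = d.min()
            return 0.30 if spacing < 30.0 else 0.08

        lat = sp.tune_lattice(self._gtv(), evaluator=evaluator)
        assert lat.goal_met
        passing = [t for t in lat.tuning_trace
                   if t["ring_v5_fraction"] <= sp.LatticePlacementConfig().ring_v5_goal]
        assert lat.tuning_trace[-1] == passing[0]


class TestMetrics:
    def _manual_lattice(self, grid, specs):
        from sfrtplan.lattice import rasterize_vtv
        vertices = [sp.Vertex(center=c, diameter=d) for c, d in specs]
        return sp.LatticeVTV(vertices, rasterize_vtv(grid, vertices))

    def test_two_vertex_hand_computation(self):
        grid = sp.VoxelGrid.centered((25, 12, 12))
        gtv = sp.ellipsoid_mask(grid, (0, 0, 0), (24, 11, 11), "GTV")
        lat = self._manual_lattice(grid, [((-12.5, 0, 0), 8.0), ((12.5, 0, 0), 12.0)])
        m = sp.lattice_metrics(lat, gtv)
        assert m.mvd == pytest.approx(10.0)
        assert m.mean_spacing == pytest.approx(25.0)
        assert m.vdsr == pytest.approx(2.5)
        assert m.vgr == pytest.approx(lat.vtv_mask.volume_cc / gtv.volume_cc)

    def test_single_vertex_spacing_undefined(self, small_grid):
        gtv = sp.sphere_mask(small_grid, (0, 0, 0), 15.0, "GTV")
        lat = self._manual_lattice(small_grid, [((0, 0, 0), 8.0)])
        m = sp.lattice_metrics(lat, gtv)
        assert m.mean_spacing is None and m.vdsr is None

    def test_default_parameters_give_vdsr_above_three(self):
        # 8 mm initial diameter at 25 mm spacing: 25/8 = 3.125, same
        # magnitude as the clinical cohort's ~3
        grid = sp.VoxelGrid.centered((30, 12, 12))
        gtv = sp.ellipsoid_mask(grid, (0, 0, 0), (29, 11, 11), "GTV")
        lat = self._manual_lattice(grid, [((-12.5, 0, 0), 8.0), ((12.5, 0, 0), 8.0)])
        assert sp.lattice_metrics(lat, gtv).vdsr == pytest.approx(3.125)

    def test_empty_lattice_rejected(self, small_grid):
        gtv = sp.sphere_mask(small_grid, (0, 0, 0), 10.0, "GTV")
        empty = sp.LatticeVTV([], sp.StructureMask(small_grid, "VTV",
                                                   np.zeros(small_grid.shape, bool)))
        with pytest.raises(ValueError):
            sp.lattice_metrics(empty, gtv)
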