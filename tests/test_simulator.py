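import numpy as np
import pytest

from puzzlecell import _geom
from puzzlecell.errors import FuncFormatError
from puzzlecell.simulator import (
    CellMesh,
    GrowthSchedule,
    SimConfig,
    apply_boundary_growth,
    divide_cells,
    load_func,
    make_template,
    place_connections,
    preset_scenarios,
    relax,
    run_simulation,
)


class TestLoadFunc:
    def test_constant(self, tmp_path):
        p = tmp_path / "const.func"
        p.write_text("0 1\n1 1\n")
        f = load_func(p)
        assert f(0.5) == pytest.approx(1.0)

    def test_step_down(self, tmp_path):
        p = tmp_path / "stepdown.func"
        p.write_text("0 1\n0.5 1\n0.5 0\n1 0\n")
        f = load_func(p)
        assert f(0.25) == pytest.approx(1.0)
        assert f(0.75) == pytest.approx(0.0)

    def test_linear_interpolation(self, tmp_path):
        p = tmp_path / "lin.func"
        p.write_text("0 0\n1 2\n")
        assert load_func(p)(0.5) == pytest.approx(1.0)

    def test_header_lines_skipped(self, tmp_path):
        p = tmp_path / "hdr.func"
        p.write_text("funcedit 1.1\nrange: 0 1\n0 1\n1 1\n")
        assert load_func(p)(0.3) == pytest.approx(1.0)

    def test_too_few_points(self, tmp_path):
        p = tmp_path / "bad.func"
        p.write_text("0 1\n")
        with pytest.raises(FuncFormatError):
            load_func(p)

    def test_decreasing_time_rejected(self, tmp_path):
        p = tmp_path / "bad.func"
        p.write_text("0 1\n0.8 1\n0.4 0\n")
        with pytest.raises(FuncFormatError):
            load_func(p)

    def test_clamped_outside_range(self, tmp_path):
        p = tmp_path / "lin.func"
        p.write_text("0 0\n1 2\n")
        f = load_func(p)
        assert f(-1.0) == pytest.approx(0.0)
        assert f(2.0) == pytest.approx(2.0)


class TestGrowthSchedule:
    def test_cumulative_scale_is_product_of_factors(self):
        sched = GrowthSchedule(np.full(50, 10 ** (1 / 50)), np.full(50, 16 ** (1 / 50)))
        sx, sy = sched.cumulative_scale()
        assert sx == pytest.approx(10.0, rel=1e-12)
        assert sy == pytest.approx(16.0, rel=1e-12)

    def test_two_phase_reaches_exact_targets(self):
        sched = GrowthSchedule.two_phase(300, 5 / 6, (10, 10), (1, 1.6))
        sx, sy = sched.cumulative_scale()
        assert sx == pytest.approx(10.0, rel=1e-9)
        assert sy == pytest.approx(16.0, rel=1e-9)

    def test_reversal_preserves_cumulative_scale(self):
        sched = GrowthSchedule.two_phase(60, 0.5, (2, 5), (3, 1.1))
        assert sched.reversed().cumulative_scale() == pytest.approx(
            sched.cumulative_scale())

    def test_from_rate_functions(self):
        sched = GrowthSchedule.from_rate_functions(
            lambda t: np.ones_like(t), lambda t: np.zeros_like(t), 100)
        sx, sy = sched.cumulative_scale()
        assert sy == pytest.approx(1.0)
        assert sx == pytest.approx((1 + 1 / 100) ** 100, rel=1e-12)


class TestTemplates:
    def test_grid_cell_count_and_area_uniformity(self):
        m = make_template("isodiametric_grid", n_cells=16, rng_seed=0)
        assert len(m.cells) == 16
        areas = [abs(_geom.signed_area(m.cell_polygon(c))) for c in m.cells]
        assert max(areas) / min(areas) < 1.2

    def test_single_cell_rim_all_boundary(self):
        m = make_template("isodiametric_grid", n_cells=1, rng_seed=0)
        assert len(m.cells) == 1
        assert m.is_boundary.all()

    def test_same_seed_identical(self):
        a = make_template("isodiametric_grid", n_cells=9, rng_seed=3)
        b = make_template("isodiametric_grid", n_cells=9, rng_seed=3)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_distinct_seeds_distinct_jitter(self):
        a = make_template("isodiametric_grid", n_cells=9, rng_seed=0)
        b = make_template("isodiametric_grid", n_cells=9, rng_seed=1)
        assert not np.allclose(a.positions, b.positions)

    def test_maize_cells_elongated(self):
        m = make_template("maize_elongated", n_cells=9, rng_seed=0, maize_aspect=6)
        for c in m.cells:
            poly = m.cell_polygon(c)
            ext = poly.max(axis=0) - poly.min(axis=0)
            assert ext[1] / ext[0] > 3

    def test_cells_tile_the_rim(self):
        m = make_template("isodiametric_grid", n_cells=25, rng_seed=2)
        rim = abs(_geom.signed_area(m.rim_polygon()))
        assert m.total_cell_area() == pytest.approx(rim, rel=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_template("isodiametric_grid", n_cells=4, cell_size=0.0)
        with pytest.raises(ValueError):
            make_template("hexagons", n_cells=4)


class TestBoundaryGrowth:
    def test_zero_growth_is_noop(self):
        m = make_template("isodiametric_grid", n_cells=4, rng_seed=0)
        before = m.positions.copy()
        apply_boundary_growth(m, 0.0, 0.0)
        np.testing.assert_array_equal(m.positions, before)

    def test_anisotropic_rim_scaling(self):
        m = make_template("isodiametric_grid", n_cells=4, rng_seed=0)
        rim0 = m.rim_polygon()
        w0 = rim0[:, 0].max() - rim0[:, 0].min()
        h0 = rim0[:, 1].max() - rim0[:, 1].min()
        apply_boundary_growth(m, 0.1, 0.0)
        rim1 = m.rim_polygon()
        assert rim1[:, 0].max() - rim1[:, 0].min() == pytest.approx(1.1 * w0)
        assert rim1[:, 1].max() - rim1[:, 1].min() == pytest.approx(h0)

    def test_compounded_steps_reach_product_scale(self):
        m = make_template("isodiametric_grid", n_cells=4, rng_seed=0)
        rim0 = m.rim_polygon()
        w0 = rim0[:, 0].max() - rim0[:, 0].min()
        fx, fy = 10 ** (1 / 30), 16 ** (1 / 30)
        for _ in range(30):
            apply_boundary_growth(m, fx - 1, fy - 1)
        rim = m.rim_polygon()
        assert rim[:, 0].max() - rim[:, 0].min() == pytest.approx(10 * w0, rel=1e-9)

    def test_interior_untouched(self):
        m = make_template("isodiametric_grid", n_cells=9, rng_seed=0)
        interior0 = m.positions[~m.is_boundary].copy()
        apply_boundary_growth(m, 0.3, 0.2)
        np.testing.assert_array_equal(m.positions[~m.is_boundary], interior0)


class TestRelax:
    def _chain(self, x_mid, k1, k2, rest1=1.0, rest2=1.0, right=3.0):
        positions = np.array([[0.0, 0], [x_mid, 0], [right, 0]])
        is_boundary = np.array([True, False, True])
        walls = {(0, 1): [rest1, k1], (1, 2): [rest2, k2]}
        return CellMesh(positions, is_boundary, walls, {},
                        growth_center=np.array([1.5, 0.0]))

    def test_all_at_rest_zero_iterations(self):
        m = self._chain(1.0, 1.0, 1.0, rest1=1.0, rest2=2.0)
        rep = relax(m, SimConfig())
        assert rep.iterations == 0
        assert rep.converged

    def test_equal_springs_middle_at_midpoint(self):
        m = self._chain(0.7, 1.0, 1.0)
        relax(m, SimConfig())
        assert m.positions[1, 0] == pytest.approx(1.5, abs=1e-4)

    def test_stiffness_ratio_closed_form(self):
        # k1 (x - l1) = k2 (L - x - l2) with k1=2, k2=1, l1=l2=1, L=3 -> x = 4/3
        m = self._chain(1.1, 2.0, 1.0)
        relax(m, SimConfig())
        assert m.positions[1, 0] == pytest.approx(4.0 / 3.0, abs=1e-4)

    def test_boundary_vertices_never_move(self):
        m = self._chain(0.4, 3.0, 1.0)
        relax(m, SimConfig())
        assert m.positions[0, 0] == 0.0
        assert m.positions[2, 0] == 3.0


class TestPlaceConnections:
    def test_convex_cell_concavity_rule_blocks_all(self):
        m = make_template("isodiametric_grid", n_cells=1, cell_size=4.0,
                          rng_seed=0, jitter=0.0)
        # every vertex is boundary; make a private interior copy of the cell
        cfg = SimConfig(require_concave=True, lec_target=1.0)
        assert place_connections(m, cfg) == 0

    def test_convex_cell_without_concavity_rule_admits(self):
        m = make_template("isodiametric_grid", n_cells=1, cell_size=2.2,
                          rng_seed=0, jitter=0.0)
        cfg = SimConfig(require_concave=False, lec_target=1.0,
                        theta_max_deg=40.0)
        assert place_connections(m, cfg) > 0

    def _dumbbell(self):
        """Two square lobes joined by a narrow neck, sampled densely."""
        outline = [
            (0, 0), (3, 0), (3, 2.4), (4, 2.4), (4, 0), (7, 0),
            (7, 6), (4, 6), (4, 3.6), (3, 3.6), (3, 6), (0, 6),
        ]
        pts = []
        for a, b in zip(outline, outline[1:] + outline[:1]):
            a, b = np.array(a, float), np.array(b, float)
            seg = max(int(np.linalg.norm(b - a) / 0.5), 1)
            for s in range(seg):
                pts.append(a + (b - a) * s / seg)
        pts = np.array(pts)
        n = len(pts)
        positions = pts
        walls = {(i, (i + 1) % n): [0.5, 1.0] for i in range(n)}
        walls = {(min(i, j), max(i, j)): v for (i, j), v in walls.items()}
        return CellMesh(positions, np.zeros(n, bool), walls,
                        {0: list(range(n))}, growth_center=pts.mean(axis=0))

    def test_dumbbell_connections_concentrate_at_neck(self):
        m = self._dumbbell()
        # the only concave vertices are the reflex corners, whose bisector
        # normals sit 45 degrees off the vertical neck chords
        cfg = SimConfig(lec_target=0.7, chord_min_factor=0.5, chord_max_factor=1.2,
                        theta_max_deg=60.0)
        added = place_connections(m, cfg)
        assert added > 0
        # all anchors should sit in the neck band (2.4 <= y <= 3.6 edges
        # flank x in [3, 4]); count anchors inside vs outside the neck third
        xs = []
        for (i, j) in m.connections:
            xs += [m.positions[i, 0], m.positions[j, 0]]
        xs = np.array(xs)
        in_neck = ((xs >= 2.5) & (xs <= 4.5)).sum()
        assert in_neck > len(xs) / 2


class TestDivisions:
    def _rect_cell(self):
        pts = []
        outline = [(0, 0), (2, 0), (2, 1), (0, 1)]
        for a, b in zip(outline, outline[1:] + outline[:1]):
            a, b = np.array(a, float), np.array(b, float)
            seg = max(int(np.linalg.norm(b - a) / 0.25), 1)
            for s in range(seg):
                pts.append(a + (b - a) * s / seg)
        pts = np.array(pts)
        n = len(pts)
        walls = {(min(i, (i + 1) % n), max(i, (i + 1) % n)): [0.25, 1.0]
                 for i in range(n)}
        return CellMesh(pts, np.zeros(n, bool), walls, {0: list(range(n))},
                        growth_center=pts.mean(axis=0))

    def test_after_division_phase_no_split(self):
        m = self._rect_cell()
        cfg = SimConfig(divisions_enabled=True, f_div=0.2, area_div=0.5)
        assert divide_cells(m, t=0.5, cfg=cfg) == 0
        assert len(m.cells) == 1

    def test_below_threshold_no_split(self):
        m = self._rect_cell()
        cfg = SimConfig(divisions_enabled=True, f_div=0.2, area_div=10.0)
        assert divide_cells(m, t=0.1, cfg=cfg) == 0

    def test_rectangle_splits_across_short_axis(self):
        m = self._rect_cell()
        cfg = SimConfig(divisions_enabled=True, f_div=0.2, area_div=1.5)
        assert divide_cells(m, t=0.1, cfg=cfg) == 1
        assert len(m.cells) == 2
        areas = [abs(_geom.signed_area(m.cell_polygon(c))) for c in m.cells]
        assert sum(areas) == pytest.approx(2.0, rel=1e-9)
        assert areas[0] == pytest.approx(areas[1], rel=0.05)
        for c in m.cells:
            poly = m.cell_polygon(c)
            ext = poly.max(axis=0) - poly.min(axis=0)
            # shortest chord through the centroid is vertical: daughters ~1x1
            assert ext[0] == pytest.approx(1.0, abs=0.05)


class TestRunSimulation:
    def test_zero_growth_leaves_template_unchanged(self):
        m = make_template("isodiametric_grid", n_cells=9, rng_seed=0)
        sched = GrowthSchedule(np.ones(8), np.ones(8))
        traj = run_simulation(m, sched, SimConfig())
        np.testing.assert_array_equal(traj.final_mesh.positions[:m.n_vertices],
                                      m.positions)

    def test_determinism_bit_identical(self):
        sched = GrowthSchedule(np.full(10, 1.5 ** (1 / 10)),
                               np.full(10, 2.0 ** (1 / 10)))
        cfg = SimConfig()
        runs = []
        for _ in range(2):
            m = make_template("isodiametric_grid", n_cells=9, rng_seed=7)
            runs.append(run_simulation(m, sched, cfg))
        np.testing.assert_array_equal(runs[0].final_mesh.positions,
                                      runs[1].final_mesh.positions)
        assert (sorted(runs[0].final_mesh.connections)
                == sorted(runs[1].final_mesh.connections))

    def test_area_tiling_preserved_under_growth(self):
        m = make_template("isodiametric_grid", n_cells=9, rng_seed=1)
        sched = GrowthSchedule(np.full(15, 2.0 ** (1 / 15)),
                               np.full(15, 2.5 ** (1 / 15)))
        traj = run_simulation(m, sched, SimConfig())
        rim = abs(_geom.signed_area(traj.final_mesh.rim_polygon()))
        assert traj.final_mesh.total_cell_area() == pytest.approx(rim, rel=0.01)

    def test_no_connections_no_lobes_under_isotropic_growth(self):
        from puzzlecell.shape_metrics import lobeyness

        m = make_template("isodiametric_grid", n_cells=9, rng_seed=0)
        sched = GrowthSchedule(np.full(20, 3.0 ** (1 / 20)),
                               np.full(20, 3.0 ** (1 / 20)))
        cfg = SimConfig(connections_enabled=False)
        traj = run_simulation(m, sched, cfg)
        lob = [lobeyness(c.vertices) for c in traj.final_contours()]
        assert max(lob) < 1.02


class TestPresets:
    def test_isodiametric_family_reaches_10_by_16(self):
        presets = preset_scenarios(n_steps=300)
        for name in ("uniform_weak_aniso", "iso_then_aniso", "aniso_then_iso"):
            sx, sy = presets[name].schedule.cumulative_scale()
            assert sx == pytest.approx(10.0, rel=1e-9), name
            assert sy == pytest.approx(16.0, rel=1e-9), name

    def test_iso_then_aniso_is_time_reversal_of_counterpart(self):
        presets = preset_scenarios(n_steps=120)
        a = presets["iso_then_aniso"].schedule
        b = presets["aniso_then_iso"].schedule
        np.testing.assert_allclose(a.factors_x[::-1], b.factors_x)
        np.testing.assert_allclose(a.factors_y[::-1], b.factors_y)

    def test_division_presets_only_divide_early(self):
        presets = preset_scenarios(n_steps=100)
        cfg = presets["iso_then_aniso_div"].config
        assert cfg.divisions_enabled
        assert cfg.f_div == pytest.approx(0.2)
        assert not presets["iso_then_aniso"].config.divisions_enabled

    def test_maize_pair_share_cumulative_scale(self):
        presets = preset_scenarios(n_steps=80)
        assert presets["maize_ordered"].schedule.cumulative_scale() == \
            pytest.approx(presets["maize_reversed"].schedule.cumulative_scale())
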