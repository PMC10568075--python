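"""Pseudo-nullcline tracing, projection, intersection finding and
classification, checked against closed forms and brute-force oracles."""

import numpy as np
import pytest

from pseudonullclines import (NullclineGeometry, SweepConfig, TraceConfig,
                              find_intersections, intersections_of, project_curve,
                              refine_and_classify, sweep_module_roots,
                              sweep_system_roots, trace_pseudo_nullcline,
                              default_projection)
from pseudonullclines.core import (ConfigurationError, CouplingMap, ModuleSpec,
                                   ParameterSet, assemble_full_system)
from pseudonullclines.nullclines import PlanarCurve, halton
from pseudonullclines.models import get_model
from pseudonullclines.models.cellcycle import cellcycle_geometry
from pseudonullclines.models.toys import fhn_v_nullcline_w, fhn_w_nullcline


def test_halton_is_deterministic_and_in_unit_box():
    a = halton(64, 3)
    b = halton(64, 3)
    np.testing.assert_array_equal(a, b)
    assert ((a >= 0) & (a < 1)).all()


class TestModuleSweeps:
    def test_single_linear_root(self):
        mod = ModuleSpec("m", ("x",), lambda x, a, p: np.array([a - x[0]]),
                         state_bounds=((-5.0, 5.0),))
        roots = sweep_module_roots(mod, 2.0, ParameterSet({}))
        assert len(roots) == 1
        np.testing.assert_allclose(roots[0], [2.0], atol=1e-9)

    def test_cellcycle_bistable_window_has_three_roots(self, cellcycle):
        """Inside the Cdk1 switch's bistable window the module has exactly the
        lower, middle and upper steady states."""
        sys = cellcycle.with_params(k_synth=1.5)
        roots = sweep_module_roots(sys.module1, 0.3, sys.params,
                                   SweepConfig(n_starts=100))
        assert len(roots) == 3

    def test_root_count_matches_dense_grid_bisection_oracle(self, cellcycle):
        """Reduce the Cdk1 module to a 1-D residual in cdk1a (the cdk1i balance
        solved in closed form) and count sign changes on a dense grid."""
        from pseudonullclines.models.cellcycle import cdk1i_at_steady_state
        sys = cellcycle.with_params(k_synth=1.5)
        p = sys.params
        for apca in [0.05, 0.15, 0.25, 0.3, 0.35, 0.5, 0.7, 0.9, 0.12, 0.28]:
            grid = np.linspace(1e-6, 700.0, 10_000)
            res = np.array([
                sys.module1.rhs_checked(
                    np.array([c, cdk1i_at_steady_state(c, apca, p)]), apca, p)[0]
                for c in grid
            ])
            oracle_count = int(np.sum(np.sign(res[:-1]) != np.sign(res[1:])))
            roots = sweep_module_roots(sys.module1, apca, p, SweepConfig(n_starts=100))
            assert len(roots) == oracle_count, f"apca={apca}"


class TestTracing:
    def test_fhn_curve_matches_analytic_cubic(self, fhn):
        pn = trace_pseudo_nullcline(fhn.module1, (-1.0, 2.0), fhn.params,
                                    TraceConfig(n_grid=200), module_id=1)
        assert pn.n_points > 0
        for br in pn.branches:
            w_pred = fhn_v_nullcline_w(br.states[:, 0], fhn.params)
            np.testing.assert_allclose(w_pred, br.inputs, atol=1e-6)
            assert br.residuals.max() <= 1e-9

    def test_folded_solution_set_yields_three_sheets(self, fhn):
        """Inputs inside the cubic's fold window must carry three solution
        branches (lower, middle, upper)."""
        pn = trace_pseudo_nullcline(fhn.module1, (0.2, 0.8), fhn.params,
                                    TraceConfig(n_grid=150), module_id=1)
        mid = 0.5
        n_here = sum(
            1 for br in pn.branches
            if br.inputs.min() <= mid <= br.inputs.max()
        )
        assert n_here == 3

    def test_grid_refinement_self_consistency(self, fhn):
        """Doubling the grid density must not move surviving points and must
        not reveal new branches."""
        coarse = trace_pseudo_nullcline(fhn.module1, (-0.5, 1.5), fhn.params,
                                        TraceConfig(n_grid=150), module_id=1)
        fine = trace_pseudo_nullcline(fhn.module1, (-0.5, 1.5), fhn.params,
                                      TraceConfig(n_grid=300), module_id=1)
        assert len(fine.branches) == len(coarse.branches)
        # every coarse point solves the same problem on the fine curve
        fine_pts = np.vstack([np.column_stack([br.inputs, br.states])
                              for br in fine.branches])
        for br in coarse.branches:
            for a, s in zip(br.inputs, br.states):
                d = np.abs(fine_pts[:, 0] - a) + np.abs(fine_pts[:, 1] - s[0])
                # fold-edge points sit at adaptively refined inputs that the
                # two grids place slightly differently
                assert d.min() < 5e-2


class TestProjection:
    def test_identity_projection_keeps_count(self, fhn):
        pn = trace_pseudo_nullcline(fhn.module1, (-1.0, 2.0), fhn.params,
                                    TraceConfig(n_grid=100), module_id=1)
        curve = project_curve(pn, lambda a, s: (a, float(s[0])), "w", "v")
        assert sum(len(b["uv"]) for b in curve.branches) == pn.n_points

    def test_affine_round_trip(self, fhn):
        pn = trace_pseudo_nullcline(fhn.module1, (-1.0, 2.0), fhn.params,
                                    TraceConfig(n_grid=60), module_id=1)
        fwd = project_curve(pn, lambda a, s: (2.0 * a + 1.0, -3.0 * s[0] + 0.5))
        for br_f, br_p in zip(fwd.branches, pn.branches):
            a_back = (br_f["uv"][:, 0] - 1.0) / 2.0
            v_back = (br_f["uv"][:, 1] - 0.5) / -3.0
            np.testing.assert_allclose(a_back, br_f["inputs"], atol=1e-12)
            np.testing.assert_allclose(v_back, br_f["states"][:, 0], atol=1e-12)

    def test_undefined_points_are_dropped(self, fhn):
        pn = trace_pseudo_nullcline(fhn.module1, (-1.0, 2.0), fhn.params,
                                    TraceConfig(n_grid=60), module_id=1)

        def partial(a, s):
            if s[0] < 0:
                raise ValueError("undefined")
            return a, float(s[0])

        curve = project_curve(pn, partial)
        assert 0 < sum(len(b["uv"]) for b in curve.branches) < pn.n_points

    def test_cellcycle_c2_low_apc_means_high_cyclin(self, cellcycle):
        """At fixed Cdk1 activity, lower APC activity means slower degradation
        and therefore more total cyclin — the mechanism that sends the APC
        curve off the plot scale at low apca."""
        from pseudonullclines.models.cellcycle import cdk1i_at_steady_state
        p = cellcycle.params
        for cdk1a in [5.0, 20.0, 60.0]:
            apcas = np.linspace(0.01, 1.0, 25)
            cyc = np.array([cdk1a + cdk1i_at_steady_state(cdk1a, a, p)
                            for a in apcas])
            assert np.all(np.diff(cyc) < 0)


def _line_curve(points, u="u", v="v"):
    pts = np.asarray(points, float)
    return PlanarCurve(1, u, v, [{"uv": pts, "states": pts[:, :1],
                                  "inputs": pts[:, 0], "branch_id": 0}])


class TestFindIntersections:
    def test_two_crossing_lines_meet_once_at_analytic_point(self):
        c1 = _line_curve([(x, 2 * x - 1) for x in np.linspace(-2, 2, 50)])
        c2 = _line_curve([(x, -x + 2) for x in np.linspace(-2, 2, 50)])
        cands = [c for c in find_intersections(c1, c2, 1e-6) if not c.grazing]
        assert len(cands) == 1
        np.testing.assert_allclose((cands[0].u, cands[0].v), (1.0, 1.0), atol=1e-9)

    def test_mismatched_planes_rejected(self):
        c1 = _line_curve([(0, 0), (1, 1)], u="a", v="b")
        c2 = _line_curve([(0, 1), (1, 0)], u="c", v="d")
        with pytest.raises(ConfigurationError):
            find_intersections(c1, c2)

    def test_grazing_contact_is_flagged_not_dropped(self):
        c1 = _line_curve([(x, 0.0) for x in np.linspace(-1, 1, 30)])
        c2 = _line_curve([(x, 5e-5) for x in np.linspace(-1, 1, 30)])
        cands = find_intersections(c1, c2, geom_tol=1e-4)
        assert cands and all(c.grazing for c in cands)


class TestRefineAndClassify:
    def test_linear_toy_matches_analytic_fixed_point(self, linear_toy):
        from pseudonullclines.models.toys import linear_toy_fixed_point
        geo = NullclineGeometry(range1=(-3, 3), range2=(-3, 3),
                                config1=TraceConfig(n_grid=100),
                                config2=TraceConfig(n_grid=100))
        its = intersections_of(linear_toy, geo)
        assert len(its) == 1
        np.testing.assert_allclose(its[0].state, linear_toy_fixed_point(linear_toy),
                                   atol=1e-9)
        assert its[0].classification == "transversal"
        assert its[0].stability == "stable_node"

    def test_fhn_intersection_equals_brute_force_root(self, fhn):
        geo = NullclineGeometry(range1=(-1.5, 2.5), range2=(-2.5, 2.5),
                                config1=TraceConfig(n_grid=150),
                                config2=TraceConfig(n_grid=150))
        its = intersections_of(fhn, geo)
        brute = sweep_system_roots(fhn, SweepConfig(n_starts=150))
        assert len(its) == len(brute) == 1
        np.testing.assert_allclose(its[0].state, brute[0], atol=1e-8)
        assert its[0].stability == "unstable_focus"

    def test_fhn_fixed_point_lies_on_both_analytic_nullclines(self, fhn):
        geo = NullclineGeometry(range1=(-1.5, 2.5), range2=(-2.5, 2.5))
        (it,) = intersections_of(fhn, geo)
        v, w = it.state
        assert abs(fhn_v_nullcline_w(v, fhn.params) - w) < 1e-9
        assert abs(fhn_w_nullcline(v, fhn.params) - w) < 1e-9


class TestCompleteness:
    @pytest.mark.parametrize("overrides,expect", [
        (dict(k_synth=0.05), 1),
        (dict(k_synth=0.04), 1),
    ])
    def test_cellcycle_intersections_equal_full_system_roots(self, overrides, expect):
        sys = get_model("cellcycle", **overrides)
        its = intersections_of(sys, cellcycle_geometry(sys.params))
        brute = sweep_system_roots(sys, SweepConfig(n_starts=400))
        assert len(its) == len(brute) == expect
        for it in its:
            d = min(np.max(np.abs(it.state - b)) for b in brute)
            assert d < 1e-6

    def test_modified_cellcycle_finds_all_three_states(self, cellcycle_modified):
        its = intersections_of(cellcycle_modified,
                               cellcycle_geometry(cellcycle_modified.params))
        brute = sweep_system_roots(cellcycle_modified, SweepConfig(n_starts=400))
        assert len(its) == len(brute) == 3
        labels = sorted(i.stability for i in its)
        assert labels == ["saddle", "saddle", "stable_node"]
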