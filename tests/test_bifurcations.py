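"""Fold/Hopf detection, tangency gap and infinite-period location, checked on
normal forms with known bifurcation points."""

import numpy as np
import pytest

from pseudonullclines import (NullclineGeometry, TraceConfig, detect_folds,
                              detect_hopf, locate_shom, scan_steady_states,
                              tangency_gap)
from pseudonullclines.core import (CouplingMap, ModuleSpec, ParameterSet,
                                   assemble_full_system)
from pseudonullclines.models import get_model


class TestFolds:
    def test_sn_normal_form_fold_at_zero(self):
        sys = get_model("sn_normal_form")
        diagram = scan_steady_states(sys, "p", np.linspace(-1, 1, 21))
        # two branches (+-sqrt(p)) for p > 0, none for p < 0
        counts = dict(zip(np.round(diagram.grid, 3), diagram.counts()))
        assert counts[-1.0] == 0 and counts[1.0] == 2
        events = detect_folds(diagram)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "SN"
        assert abs(ev.parameter - 0.0) <= 1e-7
        assert ev.diagnostics["lambda_min"] <= 1e-5

    def test_grid_halving_stability(self):
        sys = get_model("sn_normal_form")
        p1 = detect_folds(scan_steady_states(sys, "p", np.linspace(-1, 1, 11)))[0]
        p2 = detect_folds(scan_steady_states(sys, "p", np.linspace(-1, 1, 21)))[0]
        assert abs(p1.parameter - p2.parameter) < 1e-5


class TestHopf:
    def test_hopf_normal_form_crossing_at_zero(self):
        sys = get_model("hopf_normal_form")
        diagram = scan_steady_states(sys, "p", np.linspace(-0.5, 0.5, 11))
        events = detect_hopf(diagram)
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.parameter) <= 1e-6
        assert abs(ev.diagnostics["re_pair"]) <= 1e-6
        assert ev.diagnostics["omega"] == pytest.approx(sys.params["omega"], rel=1e-3)

    def test_fold_is_not_reported_as_hopf(self):
        sys = get_model("sn_normal_form")
        diagram = scan_steady_states(sys, "p", np.linspace(-1, 1, 21))
        assert detect_hopf(diagram) == []

    def test_cellcycle_lower_hopf_bracketed_by_paper_regimes(self, cellcycle):
        """Oscillation absent at k_synth = 0.04 and present at 0.05 implies a
        Hopf crossing inside (0.04, 0.05)."""
        from pseudonullclines.models.setups import pipeline_finder
        from pseudonullclines.models.cellcycle import cellcycle_geometry
        grid = np.array([0.035, 0.045, 0.055])
        diagram = scan_steady_states(
            cellcycle, "k_synth", grid,
            finder=pipeline_finder(cellcycle_geometry, "k_synth", grid))
        events = detect_hopf(diagram)
        assert len(events) == 1
        assert 0.04 < events[0].parameter < 0.05


def _parallel_lines_system(offset: float):
    """Module 1's curve is v = u - offset, module 2's is v = u: two parallel
    lines in the projected plane."""
    params = ParameterSet({"c": offset})
    m1 = ModuleSpec("x", ("x",), lambda x, a, p: np.array([a + p["c"] - x[0]]),
                    state_bounds=((-3.0, 3.0),))
    m2 = ModuleSpec("y", ("y",), lambda y, b, p: np.array([b - y[0]]),
                    state_bounds=((-3.0, 3.0),))
    cpl = CouplingMap(alpha=lambda y: float(y[0]), beta=lambda x: float(x[0]))
    return assemble_full_system(m1, m2, cpl, params, name="parallel_toy")


class TestTangencyGap:
    def test_parallel_lines_gap_equals_normalized_separation(self):
        offset = 0.5
        sys = _parallel_lines_system(offset)
        geo = NullclineGeometry(range1=(-2, 2), range2=(-2, 2),
                                config1=TraceConfig(n_grid=80),
                                config2=TraceConfig(n_grid=80))
        gap = tangency_gap(sys, geo)
        c1, c2 = geo.curves(sys)
        all_uv = np.vstack([br["uv"] for br in c1.branches + c2.branches])
        diag = float(np.hypot(*np.ptp(all_uv, axis=0)))
        expected = (offset / np.sqrt(2.0)) / diag   # perpendicular distance
        assert gap == pytest.approx(expected, rel=0.05)
        assert gap > 0

    def test_transversal_crossing_keeps_gap_positive(self, fhn):
        geo = NullclineGeometry(range1=(-1.5, 2.5), range2=(-2.5, 2.5))
        gap = tangency_gap(fhn, geo)
        assert gap > 1e-3   # curves cross, but far from tangentially

    def test_gap_vanishes_in_tangential_regime_only(self, cellcycle, cellcycle_modified):
        """The modified regime's curves touch tangentially (gap ~ 0); the
        baseline oscillator's unique crossing is transversal (gap well away
        from 0)."""
        from pseudonullclines.models.cellcycle import cellcycle_geometry
        tangential = tangency_gap(cellcycle_modified,
                                  cellcycle_geometry(cellcycle_modified.params))
        base = cellcycle.with_params(k_synth=0.05)
        transversal = tangency_gap(base, cellcycle_geometry(base.params))
        assert tangential < 5e-6
        assert transversal > 50 * tangential


class TestLocateShom:
    def test_bad_bracket_is_rejected(self, cellcycle):
        # no oscillation at either end for tiny k_synth
        with pytest.raises(ValueError):
            locate_shom(cellcycle, "k_synth", (0.005, 0.01), "cdk1a",
                        [60.0, 0.0, 0.0, 0.0], 2000.0)

    def test_infinite_period_point_at_upper_fold(self, cellcycle_modified):
        """In the modified cell cycle the oscillation is born with unbounded
        period where the stable state and the threshold saddle annihilate
        (fold on the cycle); bisection lands on that fold and the period
        diverges."""
        ev = locate_shom(cellcycle_modified, "k_synth", (1.70, 1.60), "cdk1a",
                         [60.0, 0.0, 0.0, 0.0], 9000.0,
                         bracket_tol=5e-3, period_cap_factor=2.0, t_growth=3.0)
        assert ev.type in ("SHom_candidate", "SNIC_candidate")
        assert 1.6 < ev.parameter < 1.66
        periods = [p for _, p in ev.diagnostics["periods"]]
        assert ev.diagnostics["last_period"] >= 2.0 * ev.diagnostics["base_period"]
        # period grows monotonically toward the bifurcation
        pars = [q for q, _ in ev.diagnostics["periods"]]
        order = np.argsort(pars)
        assert all(np.diff(np.array(periods)[order]) <= 1e-6)
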