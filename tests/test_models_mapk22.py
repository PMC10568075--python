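"""The 2+2 MAPK motif: mass conservation, reduction fidelity, module
bistability and the sequestration-driven oscillation."""

import numpy as np
import pytest
from scipy import optimize

from pseudonullclines import (SweepConfig, detect_limit_cycle, integrate,
                              sweep_module_roots)
from pseudonullclines.core import ConfigurationError
from pseudonullclines.models.mapk22 import (FULL_SPECIES, coupling_constants,
                                            lift_to_reduced_coords,
                                            mapk22_full_system,
                                            mapk22_reduced_system,
                                            recover_auxiliaries,
                                            reduced_initial_state)

IDX = {n: j for j, n in enumerate(FULL_SPECIES)}


class TestFullModel:
    def test_conservation_along_long_trajectory(self, mapk_full):
        """Every conserved total constant to < 1e-6 relative over 1e3 time
        units (mass action conserves them exactly; drift measures the
        integrator)."""
        traj = integrate(None, mapk_full.initial_state17(), 1000.0,
                         rhs=lambda s: mapk_full.rhs17(s), names=FULL_SPECIES)
        t0 = mapk_full.conserved_totals(traj.states[0])
        for k_ in range(0, len(traj.t), 400):
            tk = mapk_full.conserved_totals(traj.states[k_])
            for key in t0:
                assert abs(tk[key] - t0[key]) / t0[key] < 1e-6

    def test_reduced_coordinates_reproduce_full_rhs(self, mapk_full):
        rng = np.random.default_rng(3)
        for _ in range(10):
            r = rng.uniform(0, 0.05, 12)
            s = mapk_full.expand(r)
            # reduced-coordinate rhs equals the corresponding full components
            np.testing.assert_allclose(mapk_full.full_rhs(r),
                                       mapk_full.rhs17(s)[[FULL_SPECIES.index(n)
                                                           for n in mapk_full.state_names]],
                                       rtol=0, atol=0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            mapk22_full_system(k99=1.0)


class TestReduction:
    def test_coupling_identities_hold_exactly(self, mapk_reduced):
        """X = K2 + AK + ApK and Z = c1*A + c2*Ap hold identically for the
        recovered auxiliaries."""
        p = mapk_reduced.params
        c1, c2 = coupling_constants(p)
        rng = np.random.default_rng(11)
        for _ in range(25):
            k0 = rng.uniform(0, 0.3)
            x = rng.uniform(0, 0.4)
            a = rng.uniform(0, 5.0)
            app = rng.uniform(0, 8.0 - a - 0.5)
            aux = recover_auxiliaries([k0, x, a, app], p)
            assert abs(aux["K2"] + aux["CA"] + aux["CAp"] - x) < 1e-10
            assert abs(c1 * aux["A"] + c2 * aux["Ap"] - aux["Z"]) < 1e-10

    def test_equilibria_match_full_model_after_lifting(self, mapk_reduced):
        """A reduced-model steady state, lifted through the auxiliary
        recovery, Newton-polishes onto a full-network steady state that is a
        tiny correction away."""
        for e1 in [0.15, 0.4]:
            red = mapk22_reduced_system(E1tot=e1)
            full = mapk22_full_system(E1tot=e1)
            tr = integrate(red, reduced_initial_state(red.params), 2500.0)
            x4 = optimize.root(red.full_rhs, tr.endpoint, method="hybr").x
            lifted = lift_to_reduced_coords(x4, red.params)
            sol = optimize.root(full.full_rhs, lifted, method="hybr")
            assert np.max(np.abs(full.full_rhs(sol.x))) < 1e-9
            assert np.max(np.abs(sol.x - lifted)) < 1e-3

    def test_reduced_tracks_full_app_pool_to_two_percent(self):
        """Post-transient App-pool agreement between the 4-variable reduction
        and the 17-species network, matched initial conditions."""
        for e1 in [0.4, 0.15]:
            full = mapk22_full_system(E1tot=e1)
            red = mapk22_reduced_system(E1tot=e1)
            tf = integrate(None, full.initial_state17(), 2000.0,
                           rhs=lambda s: full.rhs17(s), names=FULL_SPECIES)
            tr = integrate(red, reduced_initial_state(red.params), 2000.0)
            app_full = tf.endpoint[IDX["App"]] + tf.endpoint[IDX["CAppP"]]
            app_red = tr.endpoint[3]
            assert app_red == pytest.approx(app_full, rel=0.02, abs=1e-6)

    def test_oscillation_periods_agree_between_views(self):
        full = mapk22_full_system()   # default input is inside the window
        red = mapk22_reduced_system()
        tf = integrate(None, full.initial_state17(), 2000.0,
                       rhs=lambda s: full.rhs17(s), names=FULL_SPECIES)
        tr = integrate(red, reduced_initial_state(red.params), 2000.0)
        lf = detect_limit_cycle(tf, "App")
        lr = detect_limit_cycle(tr, "App")
        assert lf.exists and lr.exists
        assert lr.period == pytest.approx(lf.period, rel=0.10)


class TestModuleBistability:
    def test_level2_module_has_folds_against_its_load(self, mapk_reduced):
        """The level-2 curve is S-shaped against the load Z: three coexisting
        steady states at heavy load, one when the load is light."""
        p = mapk_reduced.params
        counts = {Z: len(sweep_module_roots(mapk_reduced.module1, Z, p,
                                            SweepConfig(n_starts=40)))
                  for Z in [2.0, 120.0]}
        assert counts[120.0] == 3
        assert counts[2.0] == 1

    def test_level3_bistable_scanning_its_kinase(self, mapk_reduced):
        p = mapk_reduced.params
        counts = {X: len(sweep_module_roots(mapk_reduced.module2, X, p,
                                            SweepConfig(n_starts=60)))
                  for X in [0.05, 0.5, 0.8]}
        assert counts[0.5] == 3
        assert counts[0.05] == 1 and counts[0.8] == 1


class TestOscillation:
    def test_default_input_oscillates_with_narrow_peaks(self, mapk_reduced):
        traj = integrate(mapk_reduced, reduced_initial_state(mapk_reduced.params),
                         2000.0)
        lc = detect_limit_cycle(traj, "App")
        assert lc.exists
        assert lc.duty_fraction < 0.5   # output off most of each period

    def test_window_is_bounded(self):
        """No sustained oscillation well below or above the window."""
        for e1 in [0.1, 0.45]:
            red = mapk22_reduced_system(E1tot=e1)
            traj = integrate(red, reduced_initial_state(red.params), 2500.0)
            lc = detect_limit_cycle(traj, "App")
            assert not lc.exists
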