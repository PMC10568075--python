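"""Core container behaviour: parameter validation, module assembly, the
decomposition identity and Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pseudonullclines.core import (ConfigurationError, CouplingMap, ModuleSpec,
                                   ParameterSet, assemble_full_system,
                                   finite_difference_jacobian, full_jacobian)
from pseudonullclines.models import MODEL_NAMES, get_model


class TestParameterSet:
    def test_rejects_nonfinite_and_bad_totals_and_hill(self):
        with pytest.raises(ConfigurationError):
            ParameterSet({"k": float("nan")})
        with pytest.raises(ConfigurationError):
            ParameterSet({"Atot": 0.0})
        with pytest.raises(ConfigurationError):
            ParameterSet({"n_hill": 0.5})

    def test_overrides_reject_unknown_names(self):
        p = ParameterSet({"k": 1.0})
        assert p.with_overrides(k=2.0)["k"] == 2.0
        with pytest.raises(ConfigurationError):
            p.with_overrides(typo=1.0)


def test_fhn_assembly_equals_textbook_field(fhn):
    """The two 1-D modules with identity couplings reproduce the FitzHugh-
    Nagumo vector field pointwise."""
    p = fhn.params
    rng = np.random.default_rng(1)
    for _ in range(50):
        v, w = rng.uniform(-2.5, 2.5, 2)
        expected = np.array([
            v - v ** 3 / 3.0 - w + p["I_ext"],
            p["eps"] * (v + p["a_fhn"] - p["b_fhn"] * w),
        ])
        np.testing.assert_allclose(fhn.full_rhs([v, w]), expected, rtol=0, atol=0)


@pytest.mark.parametrize("name", ["cellcycle", "mapk22_reduced", "fhn_toy",
                                  "linear_toy", "sn_normal_form", "hopf_normal_form"])
def test_decomposition_identity(name):
    """full_rhs(x, y) == (f(x, alpha(y)), g(y, beta(x))) exactly, for every
    bundled model, at random admissible states."""
    sys = get_model(name)
    rng = np.random.default_rng(7)
    n1 = sys.module1.dim
    for _ in range(20):
        if name == "cellcycle":
            state = np.concatenate([rng.uniform(0, 100, 2), rng.uniform(0, 1, 2)])
        elif name == "mapk22_reduced":
            k0 = rng.uniform(0, 0.4)
            x = rng.uniform(0, 0.4)
            a = rng.uniform(0, 4.0)
            app = rng.uniform(0, 8.0 - a - 0.1)
            state = np.array([k0, x, a, app])
        else:
            state = rng.uniform(-1.5, 1.5, sys.dim)
        x, y = state[:n1], state[n1:]
        b = float(sys.coupling.beta(x))
        a = sys.coupling.alpha_at(y, b)
        expected = np.concatenate([
            sys.module1.rhs_checked(x, a, sys.params),
            sys.module2.rhs_checked(y, b, sys.params),
        ])
        np.testing.assert_array_equal(sys.full_rhs(state), expected)


def test_dimension_mismatch_is_configuration_error():
    bad = ModuleSpec("bad", ("x", "y"), lambda x, a, p: np.array([a - x[0]]))
    ok = ModuleSpec("ok", ("z",), lambda z, b, p: np.array([-z[0]]))
    cpl = CouplingMap(alpha=lambda y: float(y[0]), beta=lambda x: float(x[0]))
    with pytest.raises(ConfigurationError):
        assemble_full_system(bad, ok, cpl, ParameterSet({}))


class TestJacobian:
    def test_linear_system_recovers_matrix(self):
        A = np.array([[-1.0, 2.0], [0.5, -3.0]])
        J = finite_difference_jacobian(lambda s: A @ s, np.array([0.3, -0.7]))
        np.testing.assert_allclose(J, A, atol=1e-9)

    def test_step_halving_is_stable_on_cellcycle(self, cellcycle):
        state = np.array([30.0, 20.0, 0.4, 0.3])
        J1 = full_jacobian(cellcycle, state, rel_step=1e-6)
        J2 = full_jacobian(cellcycle, state, rel_step=5e-7)
        scale = np.abs(J1).max()
        assert np.max(np.abs(J1 - J2)) / scale < 1e-4

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(v=st.floats(-2, 2), w=st.floats(-2, 2))
    def test_fhn_jacobian_matches_analytic(self, fhn, v, w):
        p = fhn.params
        expected = np.array([[1.0 - v ** 2, -1.0],
                             [p["eps"], -p["eps"] * p["b_fhn"]]])
        J = full_jacobian(fhn, np.array([v, w]))
        np.testing.assert_allclose(J, expected, atol=1e-6)


def test_registry_knows_all_models_and_rejects_unknown():
    assert set(MODEL_NAMES) >= {"cellcycle", "mapk22_full", "mapk22_reduced",
                                "fhn_toy", "linear_toy", "sn_normal_form",
                                "hopf_normal_form"}
    with pytest.raises(ConfigurationError):
        get_model("not_a_model")
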