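"""Analytic toy systems used as oracles.

Each toy is a genuine two-module CoupledSystem whose pseudo-nullclines,
fixed points or bifurcations are available in closed form:

* ``linear_toy`` — two coupled affine 1-D modules; unique fixed point from a
  2x2 linear solve.
* ``fhn_toy`` — FitzHugh–Nagumo split into its v- and w-modules with identity
  couplings; the pseudo-nullclines coincide with the textbook cubic/linear
  nullclines.
* ``sn_normal_form`` — dx/dt = p - x^2 paired with a relaxing dummy module;
  fold at p = 0.
* ``hopf_normal_form`` — planar normal form with growth rate p; Hopf at p = 0.
"""

from __future__ import annotations

import numpy as np

from ..core import (ConfigurationError, CouplingMap, ModuleSpec, ParameterSet,
                    assemble_full_system)

__all__ = ["toy_systems", "TOY_NAMES", "fhn_v_nullcline_w", "fhn_w_nullcline"]

TOY_NAMES = ("fhn_toy", "linear_toy", "sn_normal_form", "hopf_normal_form")


def _linear_toy():
    params = ParameterSet({"k1": 1.0, "k2": 2.0, "c": 1.0})
    m1 = ModuleSpec("x", ("x",), lambda x, a, p: np.array([-p["k1"] * x[0] + a + p["c"]]),
                    state_bounds=((-10.0, 10.0),))
    m2 = ModuleSpec("y", ("y",), lambda y, b, p: np.array([-p["k2"] * y[0] + b]),
                    state_bounds=((-10.0, 10.0),))
    cpl = CouplingMap(alpha=lambda y: float(y[0]), beta=lambda x: float(x[0]),
                      alpha_label="y", beta_label="x")
    return assemble_full_system(m1, m2, cpl, params, name="linear_toy")


def linear_toy_fixed_point(system) -> np.ndarray:
    """Closed-form fixed point: x = (c k2)/(k2 k1 - 1), y = x / k2."""
    p = system.params
    x = p["c"] * p["k2"] / (p["k2"] * p["k1"] - 1.0)
    return np.array([x, x / p["k2"]])


def _fhn_toy():
    # dv/dt = v - v^3/3 - w + I ; dw/dt = eps (v + a - b w)
    params = ParameterSet({"I_ext": 0.5, "eps": 0.08, "a_fhn": 0.7, "b_fhn": 0.8})
    mv = ModuleSpec("v", ("v",),
                    lambda x, w, p: np.array([x[0] - x[0] ** 3 / 3.0 - w + p["I_ext"]]),
                    state_bounds=((-3.0, 3.0),))
    mw = ModuleSpec("w", ("w",),
                    lambda y, v, p: np.array([p["eps"] * (v + p["a_fhn"] - p["b_fhn"] * y[0])]),
                    state_bounds=((-3.0, 3.0),))
    cpl = CouplingMap(alpha=lambda y: float(y[0]), beta=lambda x: float(x[0]),
                      alpha_label="w", beta_label="v")
    return assemble_full_system(mv, mw, cpl, params, name="fhn_toy")


def fhn_v_nullcline_w(v: np.ndarray, params: ParameterSet) -> np.ndarray:
    """w on the cubic v-nullcline: w = v - v^3/3 + I."""
    v = np.asarray(v, float)
    return v - v ** 3 / 3.0 + params["I_ext"]


def fhn_w_nullcline(v: np.ndarray, params: ParameterSet) -> np.ndarray:
    """w on the linear w-nullcline: w = (v + a)/b."""
    v = np.asarray(v, float)
    return (v + params["a_fhn"]) / params["b_fhn"]


def _sn_normal_form():
    params = ParameterSet({"p": 0.5})
    m1 = ModuleSpec("x", ("x",), lambda x, a, p: np.array([p["p"] - x[0] ** 2]),
                    state_bounds=((-3.0, 3.0),))
    m2 = ModuleSpec("y", ("y",), lambda y, b, p: np.array([-y[0]]),
                    state_bounds=((-3.0, 3.0),))
    cpl = CouplingMap(alpha=lambda y: float(y[0]), beta=lambda x: float(x[0]),
                      alpha_label="y", beta_label="x")
    return assemble_full_system(m1, m2, cpl, params, name="sn_normal_form")


def _hopf_normal_form():
    # dx = p x - w y - x (x^2+y^2); dy = w x + p y - y (x^2+y^2)
    # split as two 1-D modules with identity couplings
    params = ParameterSet({"p": -0.5, "omega": 1.0})
    m1 = ModuleSpec("x", ("x",),
                    lambda x, ay, p: np.array([p["p"] * x[0] - p["omega"] * ay
                                               - x[0] * (x[0] ** 2 + ay ** 2)]),
                    state_bounds=((-3.0, 3.0),))
    m2 = ModuleSpec("y", ("y",),
                    lambda y, bx, p: np.array([p["omega"] * bx + p["p"] * y[0]
                                               - y[0] * (bx ** 2 + y[0] ** 2)]),
                    state_bounds=((-3.0, 3.0),))
    cpl = CouplingMap(alpha=lambda y: float(y[0]), beta=lambda x: float(x[0]),
                      alpha_label="y", beta_label="x")
    return assemble_full_system(m1, m2, cpl, params, name="hopf_normal_form")


_BUILDERS = {
    "fhn_toy": _fhn_toy,
    "linear_toy": _linear_toy,
    "sn_normal_form": _sn_normal_form,
    "hopf_normal_form": _hopf_normal_form,
}


def toy_systems(name: str):
    if name not in _BUILDERS:
        raise ConfigurationError(f"unknown toy system {name!r}; choose from {TOY_NAMES}")
    return _BUILDERS[name]()
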