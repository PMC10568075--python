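"""Embryonic cell-cycle oscillator (Xenopus laevis early embryo).

A four-variable relaxation oscillator built around the Cdk1–cyclin / APC
negative feedback with two positive feedbacks (Cdc25 activates Cdk1, Cdk1
inhibits Wee1):

Module 1 (Cdk1):  cdk1a, cdk1i — active and inactive Cdk1–cyclin complexes.
    Cyclin is synthesized at rate ``k_synth`` (newly formed complexes are
    active), interconverted by Cdc25/Wee1 whose activities are Hill functions
    of cdk1a scaled by the positive-feedback strength ``r``, and both forms
    are degraded at rate ``k_deg_basal + k_dest * apca``.
Module 2 (Plx1→APC): plxa, apca — active fractions of Plx1 and of the APC/C.
    Cdk1a activates Plx1, Plx1 activates APC (both Hill).  ``extra`` adds a
    basal APC activation route that does not require Plx1 (0 in the original
    model); raising it pulls the APC curve down at low Cdk1 activity, which is
    what makes tangential contacts with the Cdk1 curve reachable.

Couplings: alpha(y) = apca feeds module 1, beta(x) = cdk1a feeds module 2.
The conventional phase plane is (Cyc_tot, Cdk1a) with Cyc_tot = cdk1a + cdk1i
(total cyclin); along the APC curve, cdk1i is recovered from the Cdk1 module's
own steady-state balance at the given (cdk1a, apca).
"""

from __future__ import annotations

import numpy as np

from ..core import CouplingMap, ModuleSpec, ParameterSet, assemble_full_system
from ..nullclines import NullclineGeometry, SweepConfig, TraceConfig
from .params import load_params

__all__ = ["cellcycle_system", "cellcycle_params", "cellcycle_geometry",
           "cyctot_transform_c1", "cyctot_transform_c2", "cdk1i_at_steady_state",
           "MODIFIED_REGIME"]

# the package's saddle-node / excitability demonstration regime: strong
# positive feedback, raised Plx1 threshold, and just enough basal APC activity
# to pull the APC curve down onto the Cdk1 curve's right-hand fold
MODIFIED_REGIME = {"r": 10.0, "ec50_plx": 72.0, "extra": 0.0065}


def cellcycle_params() -> ParameterSet:
    return load_params("cellcycle")


def _hill(x, ec50, n):
    # Hill activation; undefined for negative amounts (integrator trial steps
    # can graze them), where the activity is zero
    xn = max(x, 0.0) ** n
    return xn / (ec50 ** n + xn)


def _kcdc25(c, p):
    return p["a_cdc25"] + p["r"] * p["b_cdc25"] * _hill(c, p["ec50_cdc25"], p["n_cdc25"])


def _kwee1(c, p):
    return p["a_wee1"] + p["r"] * p["b_wee1"] * (1.0 - _hill(c, p["ec50_wee1"], p["n_wee1"]))


def _kdeg(apca, p):
    return p["k_deg_basal"] + p["k_dest"] * apca


def _cdk1_rhs(x, apca, p):
    cdk1a, cdk1i = x
    kc, kw, kd = _kcdc25(cdk1a, p), _kwee1(cdk1a, p), _kdeg(apca, p)
    return np.array([
        p["k_synth"] + kc * cdk1i - kw * cdk1a - kd * cdk1a,
        kw * cdk1a - kc * cdk1i - kd * cdk1i,
    ])


def _apc_rhs(y, cdk1a, p):
    plxa, apca = y
    return np.array([
        p["k_plx_on"] * _hill(cdk1a, p["ec50_plx"], p["n_plx"]) * (p["plxtot"] - plxa)
        - p["k_plx_off"] * plxa,
        (p["k_apc_on"] * _hill(plxa, p["ec50_apc"], p["n_apc"]) + p["extra"])
        * (p["apctot"] - apca) - p["k_apc_off"] * apca,
    ])


def cellcycle_system(overrides=None, **kw):
    """The cell-cycle CoupledSystem; ``overrides``/keywords replace defaults.

    State ordering: (cdk1a, cdk1i, plxa, apca).
    """
    params = cellcycle_params().with_overrides(overrides, **kw)
    m1 = ModuleSpec("cdk1", ("cdk1a", "cdk1i"), _cdk1_rhs,
                    state_bounds=((0.0, 800.0), (0.0, 800.0)),
                    admissible=lambda x, p: x[0] >= -1e-9 and x[1] >= -1e-9)
    m2 = ModuleSpec("apc", ("plxa", "apca"), _apc_rhs,
                    state_bounds=((0.0, 1.0), (0.0, 1.0)),
                    admissible=lambda y, p: (-1e-9 <= y[0] <= p["plxtot"] + 1e-9
                                             and -1e-9 <= y[1] <= p["apctot"] + 1e-9))
    cpl = CouplingMap(alpha=lambda y: float(y[1]), beta=lambda x: float(x[0]),
                      alpha_label="apca", beta_label="cdk1a")
    return assemble_full_system(m1, m2, cpl, params, name="cellcycle")


def cdk1i_at_steady_state(cdk1a: float, apca: float, p: ParameterSet) -> float:
    """Inactive Cdk1–cyclin at the Cdk1 module's own balance, given (cdk1a, apca):
    the cdk1i equation gives cdk1i = kwee1 * cdk1a / (kcdc25 + kdeg)."""
    return _kwee1(cdk1a, p) * cdk1a / (_kcdc25(cdk1a, p) + _kdeg(apca, p))


def cellcycle_geometry(params: ParameterSet,
                       apc_range: tuple[float, float] = (0.002, 1.0),
                       cdk_range: tuple[float, float] = (0.0, 120.0)) -> NullclineGeometry:
    """Canonical (Cyc_tot, Cdk1a) curve construction for the cell-cycle model.

    The Cdk1 curve is traced over the APC input on a log grid (total cyclin
    balances synthesis against APC-driven degradation, so it sweeps
    hyperbolically in 1/apca); the APC curve over Cdk1 activity on a linear
    grid.
    """
    return NullclineGeometry(
        range1=apc_range, range2=cdk_range,
        config1=TraceConfig(n_grid=300, spacing="log",
                            sweep=SweepConfig(n_starts=64, boundary_pass=False)),
        config2=TraceConfig(n_grid=200, sweep=SweepConfig(boundary_pass=False)),
        transform1=cyctot_transform_c1(params),
        transform2=cyctot_transform_c2(params),
        labels=("cyctot", "cdk1a"), geom_tol=1e-3)


def cyctot_transform_c1(params: ParameterSet):
    """(Cyc_tot, Cdk1a) projection for the Cdk1-module curve: the traced state
    already carries both complex forms."""

    def tr(apca_input, x):
        return float(x[0] + x[1]), float(x[0])

    return tr


def cyctot_transform_c2(params: ParameterSet):
    """(Cyc_tot, Cdk1a) projection for the APC-module curve, parametrized by the
    input cdk1a: cdk1i is recovered from the Cdk1 module's steady-state relation
    at the curve's apca, so low apca maps to high Cyc_tot."""

    def tr(cdk1a_input, y):
        apca = float(y[1])
        cdk1i = cdk1i_at_steady_state(float(cdk1a_input), apca, params)
        return float(cdk1a_input + cdk1i), float(cdk1a_input)

    return tr
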