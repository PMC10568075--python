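"""The "2+2" MAPK motif: last two levels of a MAPK cascade.

Two distributive double-phosphorylation (DP) cycles in series.  The level-2
kinase K is phosphorylated twice by the input kinase E1 (K0 -> K1 -> K2,
phosphatase P2 reverses), and free doubly-phosphorylated K2 is the kinase of
the level-3 substrate A (A -> Ap -> App, phosphatase P3).  There is no
explicit feedback loop: the two levels talk to each other *forward* through
K2's activity and *backward* through sequestration — K2 bound in substrate
complexes is invisible to P2.  That retroactive load is what closes the loop
and makes oscillations possible.

Three views of the same chemistry are provided:

* ``mapk22_full_system`` — the unreduced mass-action network (17 species),
  for trajectory-level ground truth and conservation tests.  The same object
  also exposes the network in 12 *reduced coordinates* (the five conservation
  laws eliminated) so that steady states are isolated and the total input
  kinase E1tot is a genuine scan parameter.
* ``mapk22_reduced_system`` — the 4-variable two-module CoupledSystem
  (K0, X | A, App) used by the pseudo-nullcline pipeline.  X = K2 + AK + ApK
  is total doubly-phosphorylated kinase; the module-2 -> module-1 coupling
  scalar is the load Z = c1*A + c2*Ap.  Enzymes E1, P2, P3 are treated by
  Michaelis–Menten with competing substrates, kinase–substrate complexes by
  rapid equilibrium, and the level-2 conservation law is solved implicitly
  for K1 at every right-hand-side evaluation (monotone scalar equation,
  bracketed Newton).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from ..core import (ConfigurationError, CouplingMap, EvaluationError, ModuleSpec,
                    ParameterSet, assemble_full_system)
from ..nullclines import NullclineGeometry, SweepConfig, TraceConfig
from .params import load_params

__all__ = ["mapk22_params", "Mapk22Full", "mapk22_full_system",
           "mapk22_reduced_system", "mapk22_geometry", "coupling_constants",
           "recover_auxiliaries", "lift_to_reduced_coords",
           "reduced_initial_state", "FULL_SPECIES", "REDUCED_COORDS"]


def mapk22_params() -> ParameterSet:
    return load_params("mapk22")


def _km(p: ParameterSet, i: int) -> float:
    return (p[f"d{i}"] + p[f"k{i}"]) / p[f"a{i}"]


_DERIVED_CACHE: dict[tuple, tuple] = {}


def _derived(p: ParameterSet) -> tuple:
    """(Km1..Km8, c1, c2) memoized per parameter set."""
    key = tuple(sorted(p.values.items()))
    out = _DERIVED_CACHE.get(key)
    if out is None:
        kms = tuple(_km(p, i) for i in range(1, 9))
        out = kms + (1.0 / kms[4], 1.0 / kms[5])
        if len(_DERIVED_CACHE) > 4096:
            _DERIVED_CACHE.clear()
        _DERIVED_CACHE[key] = out
    return out


def coupling_constants(p: ParameterSet) -> tuple[float, float]:
    """(c1, c2) in the load Z = c1*A + c2*Ap: reciprocal Michaelis constants of
    the two K2–substrate binding steps."""
    d = _derived(p)
    return d[8], d[9]


# ---------------------------------------------------------------------------
# full mass-action network

FULL_SPECIES = ("K0", "K1", "K2", "E1", "C01", "C11", "P2", "C21", "C12",
                "A", "Ap", "App", "CA", "CAp", "P3", "CApP", "CAppP")

REDUCED_COORDS = ("K1", "K2", "C01", "C11", "C21", "C12",
                  "Ap", "App", "CA", "CAp", "CApP", "CAppP")


def _rhs17(s: np.ndarray, p: ParameterSet) -> np.ndarray:
    (K0, K1, K2, E1, C01, C11, P2, C21, C12,
     A, Ap, App, CA, CAp, P3, CApP, CAppP) = s
    # level 2: E1 phosphorylates K0 -> K1 -> K2; P2 reverses
    b1 = p["a1"] * E1 * K0 - p["d1"] * C01
    b2 = p["a2"] * E1 * K1 - p["d2"] * C11
    b3 = p["a3"] * P2 * K2 - p["d3"] * C21
    b4 = p["a4"] * P2 * K1 - p["d4"] * C12
    v1 = p["k1"] * C01
    v2 = p["k2"] * C11
    v3 = p["k3"] * C21
    v4 = p["k4"] * C12
    # level 3: free K2 phosphorylates A -> Ap -> App; P3 reverses
    b5 = p["a5"] * K2 * A - p["d5"] * CA
    b6 = p["a6"] * K2 * Ap - p["d6"] * CAp
    b7 = p["a7"] * P3 * App - p["d7"] * CAppP
    b8 = p["a8"] * P3 * Ap - p["d8"] * CApP
    v5 = p["k5"] * CA
    v6 = p["k6"] * CAp
    v7 = p["k7"] * CAppP
    v8 = p["k8"] * CApP
    return np.array([
        -b1 + v4,                                   # K0
        v1 - b2 + v3 - b4,                          # K1
        v2 - b3 - b5 + v5 - b6 + v6,                # K2
        -b1 + v1 - b2 + v2,                         # E1
        b1 - v1,                                    # C01
        b2 - v2,                                    # C11
        -b3 + v3 - b4 + v4,                         # P2
        b3 - v3,                                    # C21
        b4 - v4,                                    # C12
        -b5 + v8,                                   # A
        v5 - b6 + v7 - b8,                          # Ap
        v6 - b7,                                    # App
        b5 - v5,                                    # CA
        b6 - v6,                                    # CAp
        -b7 + v7 - b8 + v8,                         # P3
        b8 - v8,                                    # CApP
        b7 - v7,                                    # CAppP
    ])


def _expand12(r: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Reduced coordinates -> full 17-species state via the conservation laws."""
    K1, K2, C01, C11, C21, C12, Ap, App, CA, CAp, CApP, CAppP = r
    K0 = p["Ktot"] - K1 - K2 - C01 - C11 - C21 - C12 - CA - CAp
    E1 = p["E1tot"] - C01 - C11
    P2 = p["P2tot"] - C21 - C12
    P3 = p["P3tot"] - CApP - CAppP
    A = p["Atot"] - Ap - App - CA - CAp - CApP - CAppP
    return np.array([K0, K1, K2, E1, C01, C11, P2, C21, C12,
                     A, Ap, App, CA, CAp, P3, CApP, CAppP])


_R_IDX = [FULL_SPECIES.index(n) for n in REDUCED_COORDS]


@dataclass(frozen=True)
class Mapk22Full:
    """The full 2+2 network, presented in 12 reduced coordinates.

    Duck-types the pieces of CoupledSystem that the scanning machinery uses
    (``full_rhs``, ``with_params``, ``dim`` ...), with the conservation laws
    folded in so steady states are isolated and E1tot/P2tot/... are genuine
    parameters.  Raw 17-species access goes through ``rhs17`` and
    ``initial_state17``.
    """

    params: ParameterSet
    name: str = "mapk22_full"
    jac = None
    full_model = None

    @property
    def dim(self) -> int:
        return len(REDUCED_COORDS)

    @property
    def state_names(self) -> tuple[str, ...]:
        return REDUCED_COORDS

    @property
    def state_bounds(self) -> tuple[tuple[float, float], ...]:
        p = self.params
        hi = {"K1": p["Ktot"], "K2": p["Ktot"], "C01": p["E1tot"], "C11": p["E1tot"],
              "C21": p["P2tot"], "C12": p["P2tot"], "Ap": p["Atot"], "App": p["Atot"],
              "CA": p["Ktot"], "CAp": p["Ktot"], "CApP": p["P3tot"], "CAppP": p["P3tot"]}
        return tuple((0.0, hi[n]) for n in REDUCED_COORDS)

    def admissible(self, r: np.ndarray, tol: float = 1e-8) -> bool:
        """True when every species of the expanded 17-state is non-negative."""
        return bool(np.all(self.expand(np.asarray(r, float)) >= -tol))

    def with_params(self, overrides=None, **kw) -> "Mapk22Full":
        return replace(self, params=self.params.with_overrides(overrides, **kw))

    # --- 17-species view -------------------------------------------------
    def rhs17(self, s: np.ndarray, params: ParameterSet | None = None) -> np.ndarray:
        return _rhs17(np.asarray(s, float), params or self.params)

    def initial_state17(self) -> np.ndarray:
        """Everything unphosphorylated and unbound."""
        p = self.params
        s = np.zeros(17)
        s[FULL_SPECIES.index("K0")] = p["Ktot"]
        s[FULL_SPECIES.index("E1")] = p["E1tot"]
        s[FULL_SPECIES.index("P2")] = p["P2tot"]
        s[FULL_SPECIES.index("P3")] = p["P3tot"]
        s[FULL_SPECIES.index("A")] = p["Atot"]
        return s

    def conserved_totals(self, s: np.ndarray) -> dict[str, float]:
        i = {n: j for j, n in enumerate(FULL_SPECIES)}
        s = np.asarray(s, float)
        return {
            "Ktot": float(s[[i[n] for n in
                             ("K0", "K1", "K2", "C01", "C11", "C21", "C12", "CA", "CAp")]].sum()),
            "E1tot": float(s[[i["E1"], i["C01"], i["C11"]]].sum()),
            "P2tot": float(s[[i["P2"], i["C21"], i["C12"]]].sum()),
            "P3tot": float(s[[i["P3"], i["CApP"], i["CAppP"]]].sum()),
            "Atot": float(s[[i[n] for n in
                             ("A", "Ap", "App", "CA", "CAp", "CApP", "CAppP")]].sum()),
        }

    # --- reduced-coordinate view (scans) ---------------------------------
    def full_rhs(self, r: np.ndarray, params: ParameterSet | None = None) -> np.ndarray:
        p = params or self.params
        s = _expand12(np.asarray(r, float), p)
        return _rhs17(s, p)[_R_IDX]

    def expand(self, r: np.ndarray) -> np.ndarray:
        return _expand12(np.asarray(r, float), self.params)

    def project(self, s17: np.ndarray) -> np.ndarray:
        return np.asarray(s17, float)[_R_IDX]

    def output_projection(self, r: np.ndarray) -> tuple[float, float]:
        """(X, Z) of a reduced-coordinate state — the coupling plane."""
        s = self.expand(r)
        c1, c2 = coupling_constants(self.params)
        i = {n: j for j, n in enumerate(FULL_SPECIES)}
        X = float(s[i["K2"]] + s[i["CA"]] + s[i["CAp"]])
        Z = float(c1 * s[i["A"]] + c2 * s[i["Ap"]])
        return X, Z


def mapk22_full_system(overrides=None, **kw) -> Mapk22Full:
    return Mapk22Full(mapk22_params().with_overrides(overrides, **kw))


# ---------------------------------------------------------------------------
# 4-variable reduced model


_K1_WARM: dict[tuple, float] = {}


def _solve_k1(K0: float, X: float, Z: float, p: ParameterSet,
              warm: float | None = None, tol: float = 1e-12) -> float:
    """K1 from the level-2 conservation law (implicit: enzyme complexes depend
    on K1 itself).

    The residual is strictly increasing in K1, so the solve is a damped Newton
    warm-started from the previous evaluation of the same system, with a
    bracketed (brentq) fallback; converged to |residual| <= 1e-12.
    """
    Km1, Km2, Km3, Km4 = _derived(p)[:4]
    K2 = X / (1.0 + Z)
    Ktot = p["Ktot"]

    def g(K1):
        E1 = p["E1tot"] / (1.0 + K0 / Km1 + K1 / Km2)
        P2 = p["P2tot"] / (1.0 + K2 / Km3 + K1 / Km4)
        return (K0 + K1 + X + E1 * (K0 / Km1 + K1 / Km2)
                + P2 * (K2 / Km3 + K1 / Km4) - Ktot)

    glo = g(0.0)
    if glo >= 0.0:
        # conservation already exhausted by K0 + X (+ complexes): K1 -> 0.
        # Small infeasibilities happen transiently at integrator trial steps
        # near the manifold edge and are absorbed; large ones are real errors.
        if glo > 0.05 * Ktot:
            raise EvaluationError(
                f"level-2 conservation infeasible at K0={K0:.4g}, X={X:.4g}, Z={Z:.4g}")
        return 0.0

    wkey = (id(type(p)), round(p["E1tot"], 12), round(Ktot, 12))
    k1 = warm if warm is not None else _K1_WARM.get(wkey, 0.5 * Ktot)
    k1 = min(max(k1, 0.0), Ktot)
    for _ in range(50):
        gv = g(k1)
        if abs(gv) <= tol:
            _K1_WARM[wkey] = k1
            return k1
        h = 1e-7 * max(1.0, k1)
        dg = (g(k1 + h) - g(k1 - h)) / (2.0 * h)
        if dg <= 0:
            break
        step = gv / dg
        k1_new = k1 - step
        # damping: stay inside the bracket [0, Ktot]
        while k1_new < 0.0 or k1_new > Ktot:
            step *= 0.5
            k1_new = k1 - step
            if abs(step) < 1e-16:
                break
        if abs(k1_new - k1) < 1e-15 and abs(gv) > tol:
            break
        k1 = k1_new
    if g(Ktot) <= 0.0:
        raise EvaluationError("level-2 conservation residual has no sign change")
    k1 = float(brentq(g, 0.0, Ktot, xtol=1e-14, rtol=1e-13))
    _K1_WARM[wkey] = k1
    return k1


def _solve_frees(Abar: float, Appbar: float, X: float, p: ParameterSet,
                 tol: float = 1e-11, max_iter: int = 200) -> tuple[float, float, float]:
    """Free (A, Ap, App) from the level-3 pool totals.

    The reduced level-3 states are *pools*: Abar = A + AK, Appbar = App +
    AppP3, and the middle pool Atot - Abar - Appbar = Ap + ApK + ApP3.  The
    frees solve the rapid-equilibrium occupancy relations

        A   (1 + c1 K2)             = Abar
        Ap  (1 + c2 K2 + P3/Km8)    = Mbar
        App (1 + P3/Km7)            = Appbar

    with K2 = X/(1 + c1 A + c2 Ap) and P3 = P3tot/(1 + Ap/Km8 + App/Km7) —
    implicit because the enzymes' free amounts depend on the answer.  Solved
    by damped fixed-point iteration (a contraction on the occupancies), with
    a Newton fallback.
    """
    d = _derived(p)
    c1, c2, Km7, Km8 = d[8], d[9], d[6], d[7]
    # the occupancy relations extend smoothly to slightly negative pools
    # (Newton iterates and integrator trial steps graze the boundary); a hard
    # clamp would create flat plateaus that stall root finding
    margin = 1e-6 * p["Atot"]
    if Abar < -margin or Appbar < -margin or X < -margin:
        raise EvaluationError(
            f"level-3 pools out of range: Abar={Abar:.4g}, Appbar={Appbar:.4g}, X={X:.4g}")
    Mbar = p["Atot"] - Abar - Appbar
    X = max(X, 0.0)

    A, Ap, App = Abar, max(Mbar, 0.0), Appbar
    prev_err = np.inf
    damp = 0.0
    for _ in range(max_iter):
        Z = c1 * max(A, 0.0) + c2 * max(Ap, 0.0)
        K2 = X / (1.0 + Z)
        occ3 = max(Ap, 0.0) / Km8 + max(App, 0.0) / Km7
        P3 = p["P3tot"] / (1.0 + occ3)
        A_n = Abar / (1.0 + c1 * K2)
        Ap_n = Mbar / (1.0 + c2 * K2 + P3 / Km8)
        App_n = Appbar / (1.0 + P3 / Km7)
        err = max(abs(A_n - A), abs(Ap_n - Ap), abs(App_n - App))
        if err > prev_err:
            damp = 0.5  # the plain iteration is oscillating; relax it
        w = 1.0 - damp
        A, Ap, App = (damp * A + w * A_n, damp * Ap + w * Ap_n,
                      damp * App + w * App_n)
        prev_err = err
        if err <= tol * max(1.0, p["Atot"]):
            return A, Ap, App
    from scipy import optimize

    def res(v):
        A_, Ap_, App_ = v
        Z = c1 * max(A_, 0.0) + c2 * max(Ap_, 0.0)
        K2 = X / (1.0 + Z)
        P3 = p["P3tot"] / (1.0 + max(Ap_, 0.0) / Km8 + max(App_, 0.0) / Km7)
        return [A_ * (1 + c1 * K2) - Abar,
                Ap_ * (1 + c2 * K2 + P3 / Km8) - Mbar,
                App_ * (1 + P3 / Km7) - Appbar]

    sol = optimize.root(res, [A, Ap, App], method="hybr")
    if not sol.success and np.max(np.abs(res(sol.x))) > 1e-9:
        raise EvaluationError(
            f"level-3 occupancy solve failed at Abar={Abar:.4g}, Appbar={Appbar:.4g}, X={X:.4g}")
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def recover_auxiliaries(state4: np.ndarray, p: ParameterSet) -> dict[str, float]:
    """All slaved quantities of the reduced model at a state (K0, X, Abar, Appbar).

    Satisfies X = K2 + CA + CAp and Z = c1*A + c2*Ap identically (A, Ap the
    recovered free amounts).
    """
    K0, X, Abar, Appbar = (float(v) for v in state4)
    c1, c2 = coupling_constants(p)
    A, Ap, App = _solve_frees(Abar, Appbar, X, p)
    Z = c1 * A + c2 * Ap
    K2 = X / (1.0 + Z)
    K1 = _solve_k1(K0, X, Z, p)
    d = _derived(p)
    Km1, Km2, Km3, Km4, Km7, Km8 = d[0], d[1], d[2], d[3], d[6], d[7]
    E1 = p["E1tot"] / (1.0 + K0 / Km1 + K1 / Km2)
    P2 = p["P2tot"] / (1.0 + K2 / Km3 + K1 / Km4)
    P3 = p["P3tot"] / (1.0 + Ap / Km8 + App / Km7)
    return {
        "K1": K1, "K2": K2, "A": A, "Ap": Ap, "App": App, "Z": Z,
        "CA": c1 * A * K2, "CAp": c2 * Ap * K2,
        "E1": E1, "P2": P2, "P3": P3,
        "C01": E1 * K0 / Km1, "C11": E1 * K1 / Km2,
        "C21": P2 * K2 / Km3, "C12": P2 * K1 / Km4,
        "CApP": P3 * Ap / Km8, "CAppP": P3 * App / Km7,
    }


def _level2_rhs(x: np.ndarray, Z: float, p: ParameterSet) -> np.ndarray:
    K0, X = (float(v) for v in x)
    margin = 1e-6 * p["Ktot"]
    if K0 < -margin or X < -margin:
        raise EvaluationError(f"level-2 amounts out of range: K0={K0:.4g}, X={X:.4g}")
    K0, X = max(K0, 0.0), max(X, 0.0)
    K2 = X / (1.0 + Z)
    K1 = _solve_k1(K0, X, Z, p)
    Km1, Km2, Km3, Km4 = _derived(p)[:4]
    E1 = p["E1tot"] / (1.0 + K0 / Km1 + K1 / Km2)
    P2 = p["P2tot"] / (1.0 + K2 / Km3 + K1 / Km4)
    v1 = p["k1"] * E1 * K0 / Km1
    v2 = p["k2"] * E1 * K1 / Km2
    v3 = p["k3"] * P2 * K2 / Km3
    v4 = p["k4"] * P2 * K1 / Km4
    return np.array([-v1 + v4, v2 - v3])


def _level3_rhs(y: np.ndarray, X: float, p: ParameterSet) -> np.ndarray:
    Abar, Appbar = (float(v) for v in y)
    d = _derived(p)
    c1, c2, Km7, Km8 = d[8], d[9], d[6], d[7]
    A, Ap, App = _solve_frees(Abar, Appbar, X, p)
    X = max(X, 0.0)
    Z = c1 * max(A, 0.0) + c2 * max(Ap, 0.0)
    K2 = X / (1.0 + Z)
    P3 = p["P3tot"] / (1.0 + Ap / Km8 + App / Km7)
    v5 = p["k5"] * c1 * A * K2     # catalysis A -> Ap (from the AK complex)
    v6 = p["k6"] * c2 * Ap * K2    # Ap -> App
    v7 = p["k7"] * P3 * App / Km7  # App -> Ap
    v8 = p["k8"] * P3 * Ap / Km8   # Ap -> A
    # pools change by catalysis only; binding moves mass within a pool
    return np.array([-v5 + v8, v6 - v7])


def mapk22_reduced_system(overrides=None, **kw):
    """The 4-variable reduced 2+2 model as a CoupledSystem.

    State (K0, X | A, App), where the level-3 variables are *pool totals*
    (free plus complex-bound, per modification state).  Module 1's input is
    the load Z = c1*A_free + c2*Ap_free, module 2's input is X.  Both levels'
    conservation laws are implicit — free amounts are recovered from the
    pools at every right-hand-side evaluation (warm-started damped
    Newton / fixed-point solves) — which is also why the load needs the
    other module's coupling scalar X (``alpha_uses_beta``).

    Parameter overrides affecting the coupling constants must go through this
    factory, not ``with_params`` (the coupling closure captures them); the
    scan parameter E1tot is safe either way.
    """
    params = mapk22_params().with_overrides(overrides, **kw)

    def alpha(y, X):
        c1, c2 = coupling_constants(params)
        A, Ap, _ = _solve_frees(float(y[0]), float(y[1]), max(float(X), 0.0), params)
        return c1 * A + c2 * Ap

    def adm1(x, p, tol=1e-9):
        return x[0] >= -tol and x[1] >= -tol and (p["Ktot"] - x[0] - x[1]) >= -1e-6

    def adm2(y, p, tol=1e-9):
        return y[0] >= -tol and y[1] >= -tol and (p["Atot"] - y[0] - y[1]) >= -tol

    def onto_simplex(total_key, frac=0.9):
        def proj(s, p):
            tot = s[0] + s[1]
            cap = frac * p[total_key]
            return s * (cap / tot) if tot > cap else s
        return proj

    m1 = ModuleSpec("level2", ("K0", "X"), _level2_rhs,
                    state_bounds=((0.0, params["Ktot"]), (0.0, params["Ktot"])),
                    admissible=adm1, project_start=onto_simplex("Ktot"))
    m2 = ModuleSpec("level3", ("A", "App"), _level3_rhs,
                    state_bounds=((0.0, params["Atot"]), (0.0, params["Atot"])),
                    admissible=adm2, project_start=onto_simplex("Atot"))
    cpl = CouplingMap(alpha=alpha, beta=lambda x: float(x[1]),
                      alpha_label="Z", beta_label="X", alpha_uses_beta=True)
    return assemble_full_system(m1, m2, cpl, params, name="mapk22_reduced",
                                full_model=Mapk22Full(params))


def mapk22_geometry(params: ParameterSet) -> NullclineGeometry:
    """Canonical (X, Z) curve construction for the reduced 2+2 model.

    The level-2 curve is traced over the load Z on a log grid (Z spans orders
    of magnitude between the fully-loaded and converted substrate states); the
    level-3 curve over X on a linear grid.
    """
    c1, c2 = coupling_constants(params)
    z_max = 1.05 * max(c1, c2) * params["Atot"]
    return NullclineGeometry(
        range1=(1e-3, z_max), range2=(0.0, params["Ktot"]),
        config1=TraceConfig(n_grid=160, spacing="log", sweep=SweepConfig(n_starts=16)),
        config2=TraceConfig(n_grid=120, sweep=SweepConfig(n_starts=12)),
        labels=("X", "Z"), geom_tol=1e-4, refine_projected=2)


def reduced_initial_state(params: ParameterSet) -> np.ndarray:
    """All-unphosphorylated initial condition on the reduced model's manifold:
    free K0 is depressed below Ktot by the kinase bound to E1."""
    Km1 = _km(params, 1)

    def g(K0):
        E1 = params["E1tot"] / (1.0 + K0 / Km1)
        return K0 + E1 * K0 / Km1 - params["Ktot"]

    K0 = float(brentq(g, 0.0, params["Ktot"], xtol=1e-14))
    return np.array([K0, 0.0, params["Atot"], 0.0])


def lift_to_reduced_coords(state4: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Map a 4-variable reduced state to the full network's 12 reduced
    coordinates (a Newton polish turns this into a full steady state)."""
    aux = recover_auxiliaries(state4, p)
    return np.array([aux["K1"], aux["K2"], aux["C01"], aux["C11"],
                     aux["C21"], aux["C12"], aux["Ap"], aux["App"],
                     aux["CA"], aux["CAp"], aux["CApP"], aux["CAppP"]])
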