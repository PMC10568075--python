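"""Two-module coupled ODE systems.

A system is *modular* when its state splits into two blocks ``x`` and ``y``
such that each block's dynamics depend on the other block only through a
single scalar:

    dx/dt = f(x, alpha(y))
    dy/dt = g(y, beta(x))

``alpha`` and ``beta`` are the coupling functions.  Holding the scalar input
of one module fixed turns it into a stand-alone input/output system, which is
what makes pseudo-nullcline analysis possible: each module's steady-state
response curve is traced against its own scalar input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterSet",
    "ModuleSpec",
    "CouplingMap",
    "CoupledSystem",
    "assemble_full_system",
    "full_jacobian",
    "finite_difference_jacobian",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent model/config definitions."""


class EvaluationError(RuntimeError):
    """Raised when a vector field or Jacobian cannot be evaluated."""


@dataclass(frozen=True)
class ParameterSet:
    """Named map of model parameters (rate constants, Hill coefficients,
    EC50s, conserved totals).

    Conventions enforced at construction: every value is finite; names ending
    in ``tot`` (conserved totals) are strictly positive; names starting with
    ``n_`` (Hill exponents) are >= 1.
    """

    values: Mapping[str, float]

    def __post_init__(self):
        vals = dict(self.values)
        for name, v in vals.items():
            v = float(v)
            if not math.isfinite(v):
                raise ConfigurationError(f"parameter {name!r} is not finite: {v}")
            if name.endswith("tot") and v <= 0:
                raise ConfigurationError(f"total {name!r} must be > 0, got {v}")
            if name.startswith("n_") and v < 1:
                raise ConfigurationError(f"Hill exponent {name!r} must be >= 1, got {v}")
            vals[name] = v
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def keys(self):
        return self.values.keys()

    def as_dict(self) -> dict:
        return dict(self.values)

    def with_overrides(self, overrides: Mapping[str, float] | None = None, **kw) -> "ParameterSet":
        """Return a new set with some values replaced.

        Unknown names are rejected so typos in CLI/config overrides fail loudly.
        """
        new = dict(self.values)
        merged = dict(overrides or {})
        merged.update(kw)
        for name, v in merged.items():
            if name not in new:
                raise ConfigurationError(f"unknown parameter {name!r}")
            new[name] = float(v)
        return ParameterSet(new)


@dataclass(frozen=True)
class ModuleSpec:
    """One module: an ODE block ``dx/dt = rhs(x, a, params)`` with a scalar
    input ``a``.

    ``state_bounds`` give the admissible box used by deterministic multi-start
    root sweeps (they are search bounds, not hard dynamical constraints).
    """

    name: str
    state_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, float, ParameterSet], np.ndarray]
    state_bounds: tuple[tuple[float, float], ...] | None = None
    # optional predicate (state, params) -> bool rejecting unphysical roots
    # (e.g. conservation-violating solutions of the as-written equations)
    admissible: Callable[[np.ndarray, ParameterSet], bool] | None = None
    # optional map (state, params) -> state pulling multi-start seeds into the
    # feasible region (e.g. onto a conservation simplex)
    project_start: Callable[[np.ndarray, ParameterSet], np.ndarray] | None = None

    @property
    def dim(self) -> int:
        return len(self.state_names)

    def __post_init__(self):
        object.__setattr__(self, "state_names", tuple(self.state_names))
        if self.dim < 1:
            raise ConfigurationError("module must have at least one state variable")
        if self.state_bounds is not None:
            object.__setattr__(self, "state_bounds", tuple(tuple(b) for b in self.state_bounds))
            if len(self.state_bounds) != self.dim:
                raise ConfigurationError("state_bounds length must equal dim")

    def rhs_checked(self, x: np.ndarray, a: float, params: ParameterSet) -> np.ndarray:
        out = np.atleast_1d(np.asarray(self.rhs(np.asarray(x, dtype=float), float(a), params), dtype=float))
        if out.shape != (self.dim,):
            raise ConfigurationError(
                f"module {self.name!r}: rhs returned shape {out.shape}, expected ({self.dim},)"
            )
        return out


@dataclass(frozen=True)
class CouplingMap:
    """The two scalar coupling functions.

    ``alpha`` maps module-2 state -> input of module 1; ``beta`` maps
    module-1 state -> input of module 2.  In the basic case both are simply
    coordinate projections (alpha(y) = y1, beta(x) = x1); arbitrary scalar
    functions of the full module state are supported.

    ``alpha_uses_beta``: reduced models whose auxiliaries are recovered from
    conservation laws can need the *other* coupling scalar to evaluate alpha
    consistently (e.g. a sequestration load whose free amounts depend on how
    much partner is around to bind).  When set, alpha is called as
    ``alpha(y, b)`` with b = beta(x); the coupling remains a single scalar in
    each direction.
    """

    alpha: Callable[..., float]
    beta: Callable[[np.ndarray], float]
    alpha_label: str = "alpha(y)"
    beta_label: str = "beta(x)"
    alpha_uses_beta: bool = False

    def alpha_at(self, y: np.ndarray, b: float | None = None) -> float:
        if self.alpha_uses_beta:
            return float(self.alpha(y, b))
        return float(self.alpha(y))


@dataclass(frozen=True)
class CoupledSystem:
    """Two modules closed into a loop through their scalar couplings.

    Full state ordering is fixed: module-1 variables first, then module-2
    variables.  ``full_model`` optionally holds an unreduced companion system
    (e.g. the 17-species mass-action model behind a reduced 4-variable one).
    """

    module1: ModuleSpec
    module2: ModuleSpec
    coupling: CouplingMap
    params: ParameterSet
    name: str = "coupled"
    jac: Callable[[np.ndarray, ParameterSet], np.ndarray] | None = None
    full_model: object | None = None

    @property
    def dim(self) -> int:
        return self.module1.dim + self.module2.dim

    @property
    def state_names(self) -> tuple[str, ...]:
        return self.module1.state_names + self.module2.state_names

    def split(self, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        state = np.asarray(state, dtype=float)
        n1 = self.module1.dim
        return state[:n1], state[n1:]

    def admissible(self, state: np.ndarray) -> bool:
        """Conjunction of the modules' admissibility predicates (True when a
        module defines none)."""
        x, y = self.split(state)
        if self.module1.admissible is not None and not self.module1.admissible(x, self.params):
            return False
        if self.module2.admissible is not None and not self.module2.admissible(y, self.params):
            return False
        return True

    def full_rhs(self, state: np.ndarray, params: ParameterSet | None = None) -> np.ndarray:
        p = params if params is not None else self.params
        x, y = self.split(state)
        b = float(self.coupling.beta(x))
        a = self.coupling.alpha_at(y, b)
        return np.concatenate([
            self.module1.rhs_checked(x, a, p),
            self.module2.rhs_checked(y, b, p),
        ])

    def with_params(self, overrides: Mapping[str, float] | None = None, **kw) -> "CoupledSystem":
        return replace(self, params=self.params.with_overrides(overrides, **kw))


def assemble_full_system(
    module1: ModuleSpec,
    module2: ModuleSpec,
    coupling: CouplingMap,
    params: ParameterSet,
    name: str = "coupled",
    jac: Callable[[np.ndarray, ParameterSet], np.ndarray] | None = None,
    full_model: object | None = None,
) -> CoupledSystem:
    """Close two modules into a CoupledSystem.

    The returned system's right-hand side equals, exactly and by construction,
    the concatenation ``(f(x, alpha(y)), g(y, beta(x)))``.
    """
    sys = CoupledSystem(module1, module2, coupling, params, name=name, jac=jac,
                        full_model=full_model)
    # fail fast on dimension mismatches using a cheap probe state
    probe = np.ones(sys.dim)
    try:
        sys.full_rhs(probe)
    except ConfigurationError:
        raise
    except Exception:
        pass  # models may be undefined at the probe point; that is fine
    return sys


def finite_difference_jacobian(fun: Callable[[np.ndarray], np.ndarray],
                               state: np.ndarray,
                               rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian with a scale-aware step per coordinate,
    h_i = rel_step * max(1, |state_i|)."""
    state = np.asarray(state, dtype=float)
    f0 = np.asarray(fun(state), dtype=float)
    n, m = state.size, f0.size
    J = np.empty((m, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(state[i]))
        xp = state.copy(); xp[i] += h
        xm = state.copy(); xm[i] -= h
        fp = np.asarray(fun(xp), dtype=float)
        fm = np.asarray(fun(xm), dtype=float)
        J[:, i] = (fp - fm) / (2.0 * h)
    if not np.all(np.isfinite(J)):
        raise EvaluationError("non-finite Jacobian entries near state")
    return J


def full_jacobian(system: CoupledSystem, state: np.ndarray,
                  params: ParameterSet | None = None,
                  rel_step: float = 1e-6) -> np.ndarray:
    """Jacobian of the full vector field at ``state``.

    Uses the model's exact Jacobian when one was registered, otherwise
    central finite differences.
    """
    p = params if params is not None else system.params
    if system.jac is not None:
        J = np.asarray(system.jac(np.asarray(state, dtype=float), p), dtype=float)
        if J.shape != (system.dim, system.dim):
            raise ConfigurationError("registered Jacobian has wrong shape")
        return J
    return finite_difference_jacobian(lambda s: system.full_rhs(s, p), state, rel_step)
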