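"""Trajectory integration, limit-cycle detection and excitability probes.

All integration is done with stiff-capable SciPy solvers at tight tolerances;
models are evaluated as written (no state clipping), with non-negative
initial conditions keeping trajectories in the admissible domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .core import CoupledSystem, EvaluationError

logger = logging.getLogger(__name__)

__all__ = ["IntegrationConfig", "Trajectory", "LimitCycleSummary",
           "integrate", "detect_limit_cycle", "excitability_probe"]


@dataclass(frozen=True)
class IntegrationConfig:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    n_samples: int = 4000        # dense-output resolution for peak detection
    max_step: float = np.inf


@dataclass
class Trajectory:
    t: np.ndarray                # (n,)
    states: np.ndarray           # (n, dim)
    names: tuple[str, ...]
    uv: np.ndarray | None = None   # projection onto the active plane
    success: bool = True
    message: str = ""

    def observable(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]


def integrate(system, initial: Sequence[float], t_end: float,
              config: IntegrationConfig = IntegrationConfig(),
              projection: Callable | None = None,
              rhs: Callable | None = None,
              names: tuple[str, ...] | None = None) -> Trajectory:
    """Integrate a CoupledSystem (or an explicit ``rhs``) on [0, t_end].

    Output is sampled on a uniform grid dense enough for peak detection.
    Raises EvaluationError carrying the last valid time on solver failure.
    """
    x0 = np.asarray(initial, dtype=float)
    if rhs is None:
        f = lambda t, s: system.full_rhs(s)
        names = names or system.state_names
    else:
        f = lambda t, s: rhs(s)
        names = names or tuple(f"x{i}" for i in range(x0.size))
    t_eval = np.linspace(0.0, float(t_end), config.n_samples)
    sol = solve_ivp(f, (0.0, float(t_end)), x0, method=config.method,
                    rtol=config.rtol, atol=config.atol, t_eval=t_eval,
                    max_step=config.max_step)
    if not sol.success:
        raise EvaluationError(f"integration failed at t={sol.t[-1] if len(sol.t) else 0}: {sol.message}")
    states = sol.y.T
    uv = None
    if projection is not None:
        uv = np.array([projection(s) for s in states])
    return Trajectory(sol.t, states, tuple(names), uv=uv, success=True, message=sol.message)


@dataclass
class LimitCycleSummary:
    exists: bool
    period: float | None = None
    amplitude: float | None = None        # max - min of the observable over a period
    duty_fraction: float | None = None    # fraction of period above mid-range
    inconclusive: bool = False
    n_peaks: int = 0
    peak_times: np.ndarray | None = None


def _quadratic_peak(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a discrete peak by fitting a parabola through 3 points."""
    if i <= 0 or i >= len(y) - 1:
        return t[i], y[i]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return t[i], y[i]
    d = 0.5 * (y0 - y2) / denom
    dt = t[i + 1] - t[i]
    return t[i] + d * dt, y1 - 0.25 * (y0 - y2) * d


def detect_limit_cycle(traj: Trajectory, observable: str,
                       amp_floor_rel: float = 1e-3,
                       period_tol: float = 0.01,
                       transient_frac: float = 0.5) -> LimitCycleSummary:
    """Decide whether the late-time trajectory is a sustained oscillation.

    The first ``transient_frac`` of the record is discarded; a cycle is
    declared only when at least 4 post-transient peaks have spacing and height
    stable to ``period_tol`` (relative).  Quiescence is declared when the
    post-transient peak-to-peak range falls below ``amp_floor_rel`` times the
    overall variable scale.  Anything else is flagged inconclusive.
    """
    y_full = traj.observable(observable)
    scale = max(np.max(np.abs(y_full)), 1e-12)
    i0 = int(len(traj.t) * transient_frac)
    t, y = traj.t[i0:], y_full[i0:]
    if len(t) < 10:
        return LimitCycleSummary(False, inconclusive=True)
    rng = float(np.max(y) - np.min(y))
    if rng < amp_floor_rel * scale:
        return LimitCycleSummary(False, amplitude=rng)
    prom = 0.1 * rng
    peaks, _ = find_peaks(y, prominence=prom)
    if len(peaks) < 4:
        # oscillation may be too slow for the window, or decaying
        tail = y[int(0.75 * len(y)):]
        if np.max(tail) - np.min(tail) < amp_floor_rel * scale:
            return LimitCycleSummary(False, amplitude=rng)
        return LimitCycleSummary(False, inconclusive=True, n_peaks=len(peaks))
    pt = np.array([_quadratic_peak(t, y, i)[0] for i in peaks])
    ph = np.array([_quadratic_peak(t, y, i)[1] for i in peaks])
    # keep the last stretch where amplitude has settled
    periods = np.diff(pt)
    last = periods[-3:]
    if np.max(last) - np.min(last) > period_tol * np.mean(last):
        # try trimming more transient: use only final 4 peaks
        if len(pt) >= 5:
            last = np.diff(pt[-4:])
        if np.max(last) - np.min(last) > period_tol * max(np.mean(last), 1e-12):
            return LimitCycleSummary(False, inconclusive=True, n_peaks=len(peaks))
    if np.max(ph[-3:]) - np.min(ph[-3:]) > 10 * period_tol * max(abs(np.mean(ph[-3:])), 1e-12):
        return LimitCycleSummary(False, inconclusive=True, n_peaks=len(peaks))
    period = float(np.mean(last))
    # amplitude & duty over the final full period
    t1 = pt[-1]
    mask = (t >= t1 - period) & (t <= t1)
    seg = y[mask]
    amp = float(np.max(seg) - np.min(seg))
    mid = 0.5 * (np.max(seg) + np.min(seg))
    duty = float(np.mean(seg > mid))
    return LimitCycleSummary(True, period=period, amplitude=amp, duty_fraction=duty,
                             n_peaks=len(peaks), peak_times=pt)


def excitability_probe(system: CoupledSystem, saddle, stable,
                       perturbations: Sequence[Sequence[float]],
                       t_end: float, excursion_factor: float = 5.0,
                       settle_tol: float = 1e-3,
                       config: IntegrationConfig = IntegrationConfig()) -> list[dict]:
    """Classify initial conditions near a saddle as excitable or not.

    For each initial state the trajectory is integrated and compared against
    the stable steady state: a ``large_excursion`` wanders at least
    ``excursion_factor`` times the initial displacement away from the stable
    point before converging; a ``direct_return`` never does.  Trajectories that
    settle at neither listed state are flagged ``unclassified``.
    """
    if saddle.stability != "saddle":
        raise ValueError("saddle argument is not classified as a saddle")
    if not saddle.converged or not stable.converged:
        raise ValueError("both steady states must be verified (converged)")
    if not stable.stability.startswith("stable"):
        raise ValueError("stable argument is not classified as stable")
    s_star = stable.state
    out = []
    for x0 in perturbations:
        x0 = np.asarray(x0, dtype=float)
        d0 = float(np.linalg.norm(x0 - s_star))
        traj = integrate(system, x0, t_end, config)
        d = np.linalg.norm(traj.states - s_star, axis=1)
        settled = d[-1] <= max(settle_tol, 1e-9)
        if d0 == 0.0:
            verdict = "direct_return"
        elif not settled:
            verdict = "unclassified"
        elif float(np.max(d)) > excursion_factor * d0:
            verdict = "large_excursion"
        else:
            verdict = "direct_return"
        out.append({"initial": x0, "verdict": verdict,
                    "max_distance": float(np.max(d)), "initial_distance": d0,
                    "final_distance": float(d[-1]), "trajectory": traj})
    return out
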