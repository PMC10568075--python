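"""Bifurcation detection by parameter sweep + bisection.

No continuation package is replicated here: steady-state branches are scanned
on a parameter grid (all roots at every value, warm-started from neighbours),
and events are located by bisection —

* saddle-node (SN/fold): the root count changes by 2; bisected to parameter
  tolerance, then polished on the extended system (rhs = 0, smallest
  eigenvalue = 0);
* Hopf: the real part of a complex-conjugate eigenvalue pair changes sign
  along a branch; real-eigenvalue sign changes are excluded (those are folds);
* saddle-homoclinic / SNIC candidates: bisection on limit-cycle existence with
  period monitoring — the period diverges logarithmically into a homoclinic
  and as an inverse square root into a SNIC.

The *tangency gap* ties the geometry back to the pseudo-nullclines: a smooth
non-negative scalar, zero exactly where the curves touch tangentially, whose
minima over a parameter scan land on the fold parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .core import CoupledSystem, ParameterSet, full_jacobian, ConfigurationError
from .dynamics import IntegrationConfig, Trajectory, detect_limit_cycle, integrate
from .nullclines import (NullclineGeometry, PlanarCurve, SweepConfig, TraceConfig,
                         classify_eigenvalues, default_projection, project_curve,
                         sweep_system_roots, trace_pseudo_nullcline)

logger = logging.getLogger(__name__)

__all__ = ["SteadyState", "BranchDiagram", "BifurcationEvent",
           "scan_steady_states", "detect_folds", "detect_hopf",
           "tangency_gap", "locate_shom", "NullclineGeometry"]


@dataclass
class SteadyState:
    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    residual: float


@dataclass
class BifurcationEvent:
    type: str                    # "SN" | "Hopf" | "SHom_candidate" | "SNIC_candidate"
    parameter: float
    bracket: tuple[float, float]
    state: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    boundary: bool = False


class _Scanner:
    """Caches all-roots computations of a system at arbitrary parameter values."""

    def __init__(self, system: CoupledSystem, param: str,
                 finder: Callable[[CoupledSystem, list[np.ndarray]], list[np.ndarray]] | None = None,
                 sweep: SweepConfig = SweepConfig(n_starts=150),
                 dedupe_tol: float = 1e-6, root_tol: float = 1e-9):
        if param not in system.params:
            raise ConfigurationError(f"unknown scan parameter {param!r}")
        self.system = system
        self.param = param
        self.finder = finder
        self.sweep = sweep
        self.dedupe_tol = dedupe_tol
        self.root_tol = root_tol
        self._cache: dict[float, list[SteadyState]] = {}

    def at(self, value: float) -> CoupledSystem:
        return self.system.with_params({self.param: value})

    def roots_at(self, value: float, warm: Sequence[np.ndarray] = ()) -> list[SteadyState]:
        key = float(value)
        if key in self._cache:
            return self._cache[key]
        sys_v = self.at(value)
        if self.finder is not None:
            raw = self.finder(sys_v, list(warm))
        else:
            raw = sweep_system_roots(sys_v, self.sweep, extra_starts=warm)
        # polish warm starts that the finder may have missed
        states = []
        seen: list[np.ndarray] = []
        for r in raw:
            r = np.asarray(r, float)
            res = float(np.max(np.abs(sys_v.full_rhs(r))))
            if res > self.root_tol:
                sol = optimize.root(sys_v.full_rhs, r, method="hybr")
                r, res = sol.x, float(np.max(np.abs(sys_v.full_rhs(sol.x))))
                if res > self.root_tol:
                    continue
            if any(np.max(np.abs(r - s)) <= self.dedupe_tol for s in seen):
                continue
            seen.append(r)
            eigs = np.linalg.eigvals(full_jacobian(sys_v, r))
            states.append(SteadyState(r, eigs, classify_eigenvalues(eigs), res))
        states.sort(key=lambda s: tuple(np.round(s.state, 10)))
        self._cache[key] = states
        return states


@dataclass
class BranchDiagram:
    """Steady states over a parameter grid, linked into branches."""

    param: str
    grid: np.ndarray
    states: list[list[SteadyState]]           # per grid value
    branches: list[list[tuple[float, SteadyState]]]
    scanner: _Scanner

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.states])


def scan_steady_states(system: CoupledSystem, param: str, grid: Sequence[float],
                       finder: Callable | None = None,
                       sweep: SweepConfig = SweepConfig(n_starts=150),
                       root_tol: float = 1e-9) -> BranchDiagram:
    """All steady states (with stability) at each grid value, linked across
    the grid by nearest neighbour with a jump guard.

    ``finder(system_at_value, warm_starts) -> candidate states`` overrides the
    default brute-force multi-start sweep — e.g. to source candidates from the
    pseudo-nullcline pipeline of a reduced companion model.
    """
    grid = np.asarray(sorted(float(g) for g in grid))
    scanner = _Scanner(system, param, finder, sweep, root_tol=root_tol)
    per_value: list[list[SteadyState]] = []
    warm: list[np.ndarray] = []
    for g in grid:
        sts = scanner.roots_at(g, warm)
        per_value.append(sts)
        warm = [s.state for s in sts]

    # nearest-neighbour linking
    branches: list[list[tuple[float, SteadyState]]] = []
    open_ids: list[int] = []
    for g, sts in zip(grid, per_value):
        ends = {bi: branches[bi][-1][1].state for bi in open_ids}
        pairs = sorted(
            (float(np.max(np.abs(end - s.state))), bi, ri)
            for bi, end in ends.items() for ri, s in enumerate(sts)
        )
        used_b, used_r, nxt = set(), set(), []
        for d, bi, ri in pairs:
            if bi in used_b or ri in used_r:
                continue
            used_b.add(bi); used_r.add(ri)
            branches[bi].append((float(g), sts[ri]))
            nxt.append(bi)
        for ri, s in enumerate(sts):
            if ri not in used_r:
                branches.append([(float(g), s)])
                nxt.append(len(branches) - 1)
        open_ids = nxt
    return BranchDiagram(param, grid, per_value, branches, scanner)


def _lambda_min_real(eigs: np.ndarray) -> float:
    i = int(np.argmin(np.abs(eigs)))
    return float(eigs[i].real)


def _refine_fold(scanner: _Scanner, p_guess: float, x_guess: np.ndarray) -> tuple[float, np.ndarray] | None:
    """Polish a fold on the extended system (rhs(x;p)=0, lambda_min(x;p)=0)."""
    n = x_guess.size

    def ext(z):
        x, p = z[:n], z[n]
        sysp = scanner.at(p)
        r = sysp.full_rhs(x)
        eigs = np.linalg.eigvals(full_jacobian(sysp, x))
        return np.concatenate([r, [_lambda_min_real(eigs)]])

    try:
        sol = optimize.root(ext, np.concatenate([x_guess, [p_guess]]),
                            method="hybr", options={"xtol": 1e-12})
    except Exception:
        return None
    if not sol.success and np.max(np.abs(ext(sol.x))) > 1e-7:
        return None
    return float(sol.x[n]), sol.x[:n]


def detect_folds(diagram: BranchDiagram, param_tol: float = 1e-7,
                 sn_tol: float = 1e-5) -> list[BifurcationEvent]:
    """Saddle-node events from root-count changes, bisection-refined.

    Every interval where the number of steady states changes by 2 is bisected
    on root count to ``param_tol``; the coalescing pair's midpoint seeds a
    Newton polish on the extended fold system, after which the smallest
    eigenvalue magnitude is checked against ``sn_tol``.
    """
    sc = diagram.scanner
    events: list[BifurcationEvent] = []
    counts = diagram.counts()
    grid = diagram.grid
    for i in range(len(grid) - 1):
        c0, c1 = counts[i], counts[i + 1]
        if c0 == c1:
            continue
        # a fold annihilates a pair, but the grid can land exactly on the fold
        # (count changes by 1 twice); treat any change as at least one event
        n_folds = max(1, abs(int(c1) - int(c0)) // 2)
        lo, hi = float(grid[i]), float(grid[i + 1])
        for _ in range(n_folds):
            ev = _bisect_fold(sc, lo, hi, param_tol, sn_tol)
            if ev is None:
                break
            events.append(ev)
            # look for additional folds in the remaining sub-intervals
            if n_folds > 1:
                if len(sc.roots_at(lo)) != len(sc.roots_at(ev.bracket[0])):
                    hi = ev.bracket[0]
                elif len(sc.roots_at(ev.bracket[1])) != len(sc.roots_at(hi)):
                    lo = ev.bracket[1]
                else:
                    break
    # boundary folds: turning points exactly at the grid edge are not refinable
    events.sort(key=lambda e: e.parameter)
    deduped = []
    for e in events:
        if any(abs(e.parameter - d.parameter) < 10 * param_tol for d in deduped):
            continue
        deduped.append(e)
    return deduped


def _bisect_fold(sc: _Scanner, lo: float, hi: float, param_tol: float,
                 sn_tol: float) -> BifurcationEvent | None:
    n_lo = len(sc.roots_at(lo))
    n_hi = len(sc.roots_at(hi))
    if n_lo == n_hi:
        return None
    while hi - lo > param_tol:
        mid = 0.5 * (lo + hi)
        warm = [s.state for s in sc.roots_at(lo)] + [s.state for s in sc.roots_at(hi)]
        n_mid = len(sc.roots_at(mid, warm))
        if n_mid == n_lo:
            lo = mid
        else:
            hi = mid
    # coalescing pair on the root-rich side
    rich = lo if n_lo > n_hi else hi
    sts = sc.roots_at(rich)
    if not sts:
        return None
    best, pair = np.inf, None
    for a in range(len(sts)):
        for b in range(a + 1, len(sts)):
            d = float(np.max(np.abs(sts[a].state - sts[b].state)))
            if d < best:
                best, pair = d, (a, b)
    if pair is not None:
        x_guess = 0.5 * (sts[pair[0]].state + sts[pair[1]].state)
    else:
        # the bracket is already tight enough that only the marginal root is
        # visible on the rich side; seed the polish from it
        x_guess = sts[0].state
    p_mid = 0.5 * (lo + hi)
    polished = _refine_fold(sc, p_mid, x_guess)
    if polished is not None and lo - 1e-3 <= polished[0] <= hi + 1e-3:
        p_star, x_star = polished
    else:
        p_star, x_star = p_mid, x_guess
    sysp = sc.at(p_star)
    eigs = np.linalg.eigvals(full_jacobian(sysp, x_star))
    lam = float(np.min(np.abs(eigs)))
    return BifurcationEvent(
        "SN", p_star, (lo, hi), x_star,
        diagnostics={"lambda_min": lam, "lambda_min_ok": lam <= sn_tol,
                     "eigenvalues": eigs},
    )


def _complex_pair_max_re(eigs: np.ndarray, im_tol: float = 1e-9) -> float | None:
    cplx = eigs[np.abs(eigs.imag) > im_tol]
    if cplx.size == 0:
        return None
    return float(np.max(cplx.real))


def detect_hopf(diagram: BranchDiagram, param_tol: float = 1e-7,
                hopf_tol: float = 1e-6) -> list[BifurcationEvent]:
    """Hopf events: a complex-conjugate pair's real part crosses zero along a
    linked branch.  Real-eigenvalue sign changes are excluded (folds)."""
    sc = diagram.scanner
    events = []
    for br in diagram.branches:
        if len(br) < 2:
            continue
        for (p0, s0), (p1, s1) in zip(br[:-1], br[1:]):
            r0 = _complex_pair_max_re(s0.eigenvalues)
            r1 = _complex_pair_max_re(s1.eigenvalues)
            if r0 is None or r1 is None or r0 * r1 >= 0:
                continue
            lo, hi, x = p0, p1, s0.state
            re_lo = r0
            # follow the crossing pair by continuity: it may transiently
            # degenerate to a real pair inside the bracket
            e0 = s0.eigenvalues
            lam_ref = complex(e0[np.abs(e0.imag) > 1e-9][
                int(np.argmax(e0[np.abs(e0.imag) > 1e-9].real))])
            while hi - lo > param_tol:
                mid = 0.5 * (lo + hi)
                sysm = sc.at(mid)
                sol = optimize.root(sysm.full_rhs, x, method="hybr",
                                    options={"xtol": 1e-13})
                res = np.max(np.abs(sysm.full_rhs(sol.x)))
                if res > 1e-7:
                    sol = optimize.root(sysm.full_rhs, x, method="lm")
                    res = np.max(np.abs(sysm.full_rhs(sol.x)))
                    if res > 1e-7:
                        break
                x = sol.x
                eigs = np.linalg.eigvals(full_jacobian(sysm, x))
                k = int(np.argmin(np.minimum(np.abs(eigs - lam_ref),
                                             np.abs(eigs - np.conj(lam_ref)))))
                lam_ref = complex(eigs[k]) if eigs[k].imag >= 0 else complex(np.conj(eigs[k]))
                rm = float(eigs[k].real)
                if (rm > 0) == (re_lo > 0):
                    lo, re_lo = mid, rm
                else:
                    hi = mid
            p_star = 0.5 * (lo + hi)
            sysm = sc.at(p_star)
            sol = optimize.root(sysm.full_rhs, x, method="hybr")
            eigs = np.linalg.eigvals(full_jacobian(sysm, sol.x))
            re = _complex_pair_max_re(eigs)
            if re is None:
                # the pair can degenerate to a double real eigenvalue exactly
                # at the crossing; fall back to the last bracket-end value
                re = re_lo
            pair = eigs[np.abs(eigs.imag) > 1e-9]
            freq = float(np.max(np.abs(pair.imag))) if pair.size else 0.0
            events.append(BifurcationEvent(
                "Hopf", p_star, (lo, hi), sol.x,
                diagnostics={"re_pair": re, "re_ok": abs(re) <= hopf_tol,
                             "omega": freq, "eigenvalues": eigs}))
    events.sort(key=lambda e: e.parameter)
    deduped = []
    for e in events:
        if any(abs(e.parameter - d.parameter) < 10 * param_tol for d in deduped):
            continue
        deduped.append(e)
    return deduped


# ---------------------------------------------------------------------------
# tangency geometry


def tangency_gap(system: CoupledSystem, geometry: NullclineGeometry,
                 contact_radius_frac: float = 0.02) -> float:
    """Smooth non-negative closeness-to-tangency of the two projected curves.

    For every point of C1, combine its normalized perpendicular distance to C2
    with the tangent misalignment (1 - |cos theta|) at the nearest C2 segment;
    the gap is the minimum of the sum.  It vanishes exactly at a tangential
    contact: a transversal crossing keeps the alignment term positive, while
    separated curves keep the distance term positive (two parallel lines
    yield exactly their normalized separation).
    """
    c1, c2 = geometry.curves(system)
    if not c1.branches or not c2.branches:
        return float("nan")
    all_uv = np.vstack([br["uv"] for br in c1.branches + c2.branches])
    span = np.ptp(all_uv, axis=0)
    diag = float(np.hypot(*span)) or 1.0

    # C2 as one segment soup (a, b) with unit tangents
    segs_a, segs_b = [], []
    for br in c2.branches:
        uv = br["uv"]
        if len(uv) >= 2:
            segs_a.append(uv[:-1])
            segs_b.append(uv[1:])
    if not segs_a:
        return float("nan")
    a = np.vstack(segs_a)                       # (M, 2)
    b = np.vstack(segs_b)
    ab = b - a
    ab_len2 = np.einsum("ij,ij->i", ab, ab)
    ab_len2[ab_len2 == 0] = 1.0
    t2 = ab / np.sqrt(ab_len2)[:, None]

    best = np.inf
    for br in c1.branches:
        uv = br["uv"]
        if len(uv) < 2:
            continue
        t1 = np.gradient(uv, axis=0)
        n1 = np.linalg.norm(t1, axis=1, keepdims=True)
        n1[n1 == 0] = 1.0
        t1 = t1 / n1
        # point-to-segment distances, all pairs at once
        ap = uv[:, None, :] - a[None, :, :]                 # (N, M, 2)
        t = np.einsum("nmi,mi->nm", ap, ab) / ab_len2
        t = np.clip(t, 0.0, 1.0)
        proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d = np.linalg.norm(uv[:, None, :] - proj, axis=2)   # (N, M)
        j = np.argmin(d, axis=1)
        dmin = d[np.arange(len(uv)), j]
        align = 1.0 - np.abs(np.einsum("ni,ni->n", t1, t2[j]))
        val = float(np.min(dmin / diag + align))
        if val < best:
            best = val
    return float(best)


# ---------------------------------------------------------------------------
# saddle-homoclinic / SNIC location


def locate_shom(system: CoupledSystem, param: str,
                bracket: tuple[float, float], observable: str,
                initial: Sequence[float], t_end: float,
                config: IntegrationConfig = IntegrationConfig(),
                bracket_tol: float = 1e-3, period_cap_factor: float = 20.0,
                saddle_checker: Callable[[CoupledSystem], bool] | None = None,
                sn_values: Sequence[float] = (), sn_coincidence_tol: float = 1e-3,
                t_growth: float = 4.0, max_horizon: float | None = None) -> BifurcationEvent:
    """Locate an infinite-period (saddle-homoclinic or SNIC) bifurcation by
    bisection on limit-cycle existence, monitoring the period.

    ``bracket`` must have a sustained oscillation at one end and none at the
    other.  The integration horizon is stretched by ``t_growth`` whenever the
    cycle test is inconclusive (periods diverge near the global bifurcation).

    Labelling: a located point that coincides (within ``sn_coincidence_tol``)
    with a known fold parameter in ``sn_values`` is a ``SNIC_candidate`` (the
    saddle-node sits on the cycle); otherwise ``SHom_candidate`` when a
    separate saddle exists at the located parameter (``saddle_checker``), and
    ``SNIC_candidate`` when none does.  Candidates, not certificates: the
    curve geometry narrows the diagnosis but only the period scaling law and
    the eigenvalues settle it.
    """
    from dataclasses import replace as _replace

    lo, hi = sorted((float(bracket[0]), float(bracket[1])))
    t_base = float(t_end)
    t_cap = float(max_horizon) if max_horizon is not None else 16.0 * t_base

    def cycle_at(p: float, x0, t_hor):
        sysp = system.with_params({param: p})
        t_hor = min(t_hor, t_cap)

        def run(t):
            # keep the sampling density roughly constant as the horizon grows
            n = int(min(60_000, config.n_samples * max(1.0, t / t_base)))
            return integrate(sysp, x0, t, _replace(config, n_samples=n))

        traj = run(t_hor)
        lc = detect_limit_cycle(traj, observable)
        tries = 0
        while lc.inconclusive and tries < 3 and t_hor < t_cap:
            t_hor = min(t_hor * t_growth, t_cap)
            traj = run(t_hor)
            lc = detect_limit_cycle(traj, observable)
            tries += 1
        return lc, traj, t_hor

    lc_lo, traj_lo, _ = cycle_at(lo, initial, t_end)
    lc_hi, traj_hi, _ = cycle_at(hi, initial, t_end)
    if lc_lo.exists == lc_hi.exists:
        raise ValueError("bracket must have oscillation on exactly one end "
                         f"(got exists={lc_lo.exists} at both ends)")
    osc_low = lc_lo.exists
    base_period = (lc_lo.period if osc_low else lc_hi.period)
    periods = [((lo if osc_low else hi), base_period)]
    x_cycle = (traj_lo if osc_low else traj_hi).endpoint
    t_hor = t_end
    last_period = base_period

    while hi - lo > bracket_tol or last_period < period_cap_factor * base_period:
        if hi - lo <= max(bracket_tol * 1e-3, 1e-12):
            break  # cannot tighten further; period cap unreachable
        mid = 0.5 * (lo + hi)
        lc, traj, t_hor = cycle_at(mid, x_cycle, t_hor)
        if lc.exists:
            periods.append((mid, lc.period))
            last_period = lc.period
            x_cycle = traj.endpoint
            if osc_low:
                lo = mid
            else:
                hi = mid
        else:
            if osc_low:
                hi = mid
            else:
                lo = mid

    if last_period < period_cap_factor * base_period:
        # bisection may have probed only the quiescent side; measure the period
        # at the oscillatory end of the final (tight) bracket
        p_osc = lo if osc_low else hi
        lc, traj, t_hor = cycle_at(p_osc, x_cycle, t_hor)
        if lc.exists:
            periods.append((p_osc, lc.period))
            last_period = lc.period

    p_star = 0.5 * (lo + hi)
    if any(abs(p_star - s) <= sn_coincidence_tol for s in sn_values):
        etype = "SNIC_candidate"
    elif saddle_checker is not None and saddle_checker(system.with_params({param: p_star})):
        etype = "SHom_candidate"
    else:
        etype = "SNIC_candidate"
    periods.sort()
    return BifurcationEvent(
        etype, p_star, (lo, hi),
        diagnostics={"periods": periods, "base_period": base_period,
                     "last_period": last_period,
                     "period_ratio": last_period / base_period if base_period else np.nan})
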