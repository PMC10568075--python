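"""Pseudo-nullcline construction and intersection analysis.

For a two-module system, each module's *pseudo-nullcline* is the set of its
steady states traced against its scalar input, projected onto the plane
spanned by the two coupling scalars.  Steady states of the coupled system lie
exactly on the intersections of the two curves; a *tangential* intersection
signals a limit-point (saddle-node) bifurcation, while transversal
intersections behave like ordinary nullcline crossings.

Branches are traced by deterministic multi-start root sweeps on a grid of
input values followed by nearest-neighbour linking — not by arclength
continuation — so disconnected branches and folded (S-shaped) solution sets
are picked up without special casing: at every input, *all* sheets are found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

from .core import (ConfigurationError, CoupledSystem, ModuleSpec, ParameterSet,
                   full_jacobian)

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig", "TraceConfig", "CurveBranch", "PseudoNullcline",
    "PlanarCurve", "Candidate", "Intersection",
    "halton", "sweep_module_roots", "sweep_system_roots",
    "trace_pseudo_nullcline", "project_curve", "default_projection",
    "find_intersections", "refine_and_classify", "classify_eigenvalues",
    "NullclineGeometry", "intersections_of",
]

# ---------------------------------------------------------------------------
# deterministic multi-start machinery


def halton(n: int, dim: int, skip: int = 20) -> np.ndarray:
    """First ``n`` points of the Halton low-discrepancy sequence in [0,1)^dim.

    Deterministic by construction; used everywhere a multi-start grid is
    needed so that repeated runs are bit-identical.
    """
    primes = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37]
    if dim > len(primes):
        raise ConfigurationError("halton: dimension too large")
    out = np.empty((n, dim))
    for d in range(dim):
        b = primes[d]
        for i in range(n):
            k, f, r = skip + i + 1, 1.0, 0.0
            while k > 0:
                f /= b
                r += f * (k % b)
                k //= b
            out[i, d] = r
    return out


@dataclass(frozen=True)
class SweepConfig:
    """Multi-start root sweep settings for one module.

    ``boundary_pass`` adds a bounded least-squares pass seeded at the box
    corners — needed when roots sit pressed against the admissible boundary
    (saturated chemistry); skippable for models with interior roots.
    """

    n_starts: int = 40
    root_tol: float = 1e-9
    dedupe_tol: float = 1e-6
    max_iter: int = 200
    boundary_pass: bool = True

    def starts(self, bounds: Sequence[tuple[float, float]]) -> np.ndarray:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        pts = halton(self.n_starts, len(bounds))
        return lo + pts * (hi - lo)


def _dedupe(roots: list[np.ndarray], tol: float) -> list[np.ndarray]:
    kept: list[np.ndarray] = []
    for r in roots:
        if not any(np.max(np.abs(r - k)) <= tol for k in kept):
            kept.append(r)
    # stable deterministic order: sort by coordinates
    kept.sort(key=lambda r: tuple(np.round(r, 12)))
    return kept


def _newton_roots(fun, starts: Iterable[np.ndarray], root_tol: float,
                  dedupe_tol: float, accept=None) -> list[np.ndarray]:
    roots = []
    for s in starts:
        try:
            sol = optimize.root(fun, s, method="hybr", options={"xtol": 1e-12})
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        res = np.max(np.abs(fun(sol.x)))
        if res <= root_tol and (accept is None or accept(sol.x)):
            roots.append(sol.x.astype(float))
    return _dedupe(roots, dedupe_tol)


def _boundary_starts(bounds: Sequence[tuple[float, float]]) -> list[np.ndarray]:
    """Deterministic corner / edge-midpoint / center seeds.  Fixed points of
    saturated chemical modules often sit near the boundary of the admissible
    box, where interior Newton basins are tiny."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    mid = 0.5 * (lo + hi)
    dim = len(bounds)
    out = [mid.copy()]
    if dim <= 4:
        for mask in range(2 ** dim):
            pt = np.where([(mask >> i) & 1 for i in range(dim)], hi, lo).astype(float)
            out.append(pt)
    return out


def _ls_roots(fun, starts, bounds, root_tol, accept) -> list[np.ndarray]:
    """Bounded least-squares refinement; robust where a root sits against the
    admissible boundary and plain Newton wanders off."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    roots = []
    for s in starts:
        s = np.clip(np.asarray(s, float), lo, hi)
        try:
            sol = optimize.least_squares(fun, s, bounds=(lo, hi), max_nfev=100,
                                         xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        res = float(np.max(np.abs(fun(sol.x))))
        if res <= root_tol and (accept is None or accept(sol.x)):
            roots.append(sol.x.astype(float))
    return roots


def sweep_module_roots(module: ModuleSpec, input_value: float,
                       params: ParameterSet,
                       sweep: SweepConfig = SweepConfig(),
                       bounds: Sequence[tuple[float, float]] | None = None,
                       extra_starts: Iterable[np.ndarray] = (),
                       accept=None) -> list[np.ndarray]:
    """All distinct steady states of one module at a fixed scalar input.

    Multistable modules return several roots; an empty list means no start
    converged (the caller decides whether that is an error).  ``accept``
    optionally rejects inadmissible roots (e.g. negative concentrations).
    """
    if bounds is None:
        bounds = module.state_bounds
    if bounds is None:
        raise ConfigurationError(f"module {module.name!r} has no state bounds for sweeping")

    def fun(x):
        try:
            return module.rhs_checked(x, input_value, params)
        except Exception:
            return np.full(module.dim, 1e6)

    if accept is None and module.admissible is not None:
        accept = lambda x: module.admissible(x, params)
    starts = list(sweep.starts(bounds)) + [np.asarray(s, float) for s in extra_starts]
    if module.project_start is not None:
        starts = [module.project_start(np.asarray(s, float), params) for s in starts]
    roots = _newton_roots(fun, starts, sweep.root_tol, sweep.dedupe_tol, accept)
    if sweep.boundary_pass:
        # boundary-seeded bounded pass: catches roots pressed against the
        # admissible box that interior Newton misses
        roots += _ls_roots(fun, _boundary_starts(bounds), bounds, sweep.root_tol, accept)
    return _dedupe(roots, sweep.dedupe_tol)


def sweep_system_roots(system: CoupledSystem,
                       sweep: SweepConfig = SweepConfig(n_starts=200),
                       bounds: Sequence[tuple[float, float]] | None = None,
                       extra_starts: Iterable[np.ndarray] = (),
                       accept=None) -> list[np.ndarray]:
    """Brute-force multi-start root sweep on the *full* coupled system.

    Serves as the independent cross-check for the pseudo-nullcline pipeline:
    every refined intersection must appear here and vice versa.  The system's
    own ``admissible`` predicate (if any) filters unphysical roots unless an
    explicit ``accept`` is given.
    """
    if bounds is None:
        bounds = getattr(system, "state_bounds", None)
    if bounds is None:
        b1 = system.module1.state_bounds
        b2 = system.module2.state_bounds
        if b1 is None or b2 is None:
            raise ConfigurationError("system modules need state bounds for sweeping")
        bounds = tuple(b1) + tuple(b2)
    if accept is None:
        accept = getattr(system, "admissible", None)

    def fun(s):
        try:
            return system.full_rhs(s)
        except Exception:
            return np.full(system.dim, 1e6)

    starts = list(sweep.starts(bounds)) + [np.asarray(s, float) for s in extra_starts]
    return _newton_roots(fun, starts, sweep.root_tol, sweep.dedupe_tol, accept)


# ---------------------------------------------------------------------------
# branch tracing


@dataclass
class CurveBranch:
    """One connected sheet of a module's steady-state solution set.

    ``inputs[i]`` is the scalar input value and ``states[i]`` the module
    steady state solving ``rhs(state, input) = 0`` there.
    """

    branch_id: int
    inputs: np.ndarray          # (n,)
    states: np.ndarray          # (n, dim)
    residuals: np.ndarray       # (n,)

    def __len__(self):
        return len(self.inputs)


@dataclass
class PseudoNullcline:
    """All solution branches of one module over a scanned input range."""

    module_id: int              # 1 or 2
    module_name: str
    branches: list[CurveBranch]
    input_range: tuple[float, float]

    @property
    def n_points(self) -> int:
        return sum(len(b) for b in self.branches)


@dataclass(frozen=True)
class TraceConfig:
    n_grid: int = 240
    sweep: SweepConfig = field(default_factory=SweepConfig)
    # adaptive refinement: bisect input intervals where the root count changes
    # (fold neighbourhoods)
    max_refine: int = 8
    # input grid spacing: "linear" or "log" (log needs a positive input range;
    # right for curves that sweep hyperbolically, e.g. balance ~ 1/input)
    spacing: str = "linear"
    # linking: a root continues a branch if it is the mutual nearest neighbour
    # and the state jump is below jump_tol (absolute, max-norm)
    jump_tol: float = np.inf

    def make_grid(self, a_lo: float, a_hi: float) -> list[float]:
        if self.spacing == "log":
            if a_lo <= 0:
                raise ConfigurationError("log spacing needs a positive input range")
            return list(np.geomspace(a_lo, a_hi, self.n_grid))
        return list(np.linspace(a_lo, a_hi, self.n_grid))


def _sweep_cache_roots(module, params, cfg: TraceConfig, bounds, cache, a, warm):
    key = float(a)
    if key not in cache:
        cache[key] = sweep_module_roots(module, a, params, cfg.sweep, bounds,
                                        extra_starts=warm)
    return cache[key]


def trace_pseudo_nullcline(module: ModuleSpec, input_range: tuple[float, float],
                           params: ParameterSet,
                           config: TraceConfig = TraceConfig(),
                           module_id: int = 1,
                           bounds: Sequence[tuple[float, float]] | None = None,
                           grid: Sequence[float] | None = None,
                           cache: dict | None = None) -> PseudoNullcline:
    """Trace all steady-state branches of ``module`` over ``input_range``.

    Folded (S-shaped) solution sets come out as separate sheets covering the
    lower, middle and upper branches, because the multi-start sweep finds all
    roots at every grid value; nearest-neighbour linking with a jump guard
    then assembles sheets.  Grid intervals where the root count changes are
    bisected up to ``config.max_refine`` times so fold edges are sharp.
    """
    a_lo, a_hi = float(input_range[0]), float(input_range[1])
    if not np.isfinite([a_lo, a_hi]).all() or a_hi <= a_lo:
        raise ConfigurationError("input_range must be a finite increasing interval")
    grid = sorted(float(g) for g in grid) if grid is not None else config.make_grid(a_lo, a_hi)
    if cache is None:
        cache = {}

    # initial pass with warm starts from the previous grid point
    warm: list[np.ndarray] = []
    for a in grid:
        roots = _sweep_cache_roots(module, params, config, bounds, cache, a, warm)
        warm = roots

    # adaptive bisection where the root count changes between neighbours
    for _ in range(config.max_refine):
        grid.sort()
        new_pts = []
        for a0, a1 in zip(grid[:-1], grid[1:]):
            if len(cache[float(a0)]) != len(cache[float(a1)]) and (a1 - a0) > 1e-9 * (a_hi - a_lo):
                new_pts.append(0.5 * (a0 + a1))
        if not new_pts:
            break
        for a in new_pts:
            lo_roots = cache[float(max(g for g in grid if g < a))]
            _sweep_cache_roots(module, params, config, bounds, cache, a, lo_roots)
            grid.append(a)

    grid.sort()

    # nearest-neighbour linking into branches
    branches: list[list[tuple[float, np.ndarray]]] = []
    open_branches: list[int] = []
    for a in grid:
        roots = cache[float(a)]
        ends = {bi: branches[bi][-1][1] for bi in open_branches}
        # greedy mutual-nearest matching
        pairs = []
        for bi, end in ends.items():
            for ri, r in enumerate(roots):
                d = float(np.max(np.abs(end - r)))
                if d <= config.jump_tol:
                    pairs.append((d, bi, ri))
        pairs.sort(key=lambda t: (t[0], t[1], t[2]))
        used_b, used_r = set(), set()
        next_open = []
        for d, bi, ri in pairs:
            if bi in used_b or ri in used_r:
                continue
            used_b.add(bi); used_r.add(ri)
            branches[bi].append((a, roots[ri]))
            next_open.append(bi)
        for ri, r in enumerate(roots):
            if ri not in used_r:
                branches.append([(a, r)])
                next_open.append(len(branches) - 1)
        open_branches = next_open

    out: list[CurveBranch] = []
    for bid, pts in enumerate(branches):
        if not pts:
            continue
        inputs = np.array([p[0] for p in pts])
        states = np.array([p[1] for p in pts])
        res = np.array([
            float(np.max(np.abs(module.rhs_checked(s, a, params))))
            for a, s in pts
        ])
        out.append(CurveBranch(bid, inputs, states, res))
    if not out:
        logger.warning("empty pseudo-nullcline for module %s over %s", module.name, input_range)
    return PseudoNullcline(module_id, module.name, out, (a_lo, a_hi))


# ---------------------------------------------------------------------------
# projection


@dataclass
class PlanarCurve:
    """A pseudo-nullcline projected to a 2-D plane, with provenance.

    Each branch keeps, per point: planar (u, v), the source module state and
    the source input value — so intersection candidates can be lifted back to
    full-state initial guesses.
    """

    module_id: int
    u_label: str
    v_label: str
    branches: list[dict]        # keys: uv (n,2), states (n,dim), inputs (n,)

    @property
    def plane(self) -> tuple[str, str]:
        return (self.u_label, self.v_label)


def default_projection(system: CoupledSystem, module_id: int) -> Callable:
    """The canonical plane: (coupling scalar of module 1, coupling scalar of
    module 2), i.e. horizontal = beta(x), vertical = alpha(y).

    For module 1 the vertical coordinate is its *input*; for module 2 the
    horizontal one is.
    """
    if module_id == 1:
        return lambda a, x: (float(system.coupling.beta(x)), float(a))
    # for module 2 the horizontal coordinate is its input b = beta(x), which is
    # also what a beta-aware alpha needs
    return lambda b, y: (float(b), system.coupling.alpha_at(y, float(b)))


def project_curve(pnc: PseudoNullcline, transform: Callable,
                  u_label: str = "u", v_label: str = "v") -> PlanarCurve:
    """Apply ``transform(input_value, state) -> (u, v)`` to every branch point.

    Points where the transform is undefined (raises or returns non-finite)
    are dropped with a log entry.
    """
    branches = []
    for br in pnc.branches:
        uv, st, ins = [], [], []
        for a, s in zip(br.inputs, br.states):
            try:
                u, v = transform(a, s)
            except Exception:
                logger.info("projection undefined at input=%g; point dropped", a)
                continue
            if not (np.isfinite(u) and np.isfinite(v)):
                logger.info("projection non-finite at input=%g; point dropped", a)
                continue
            uv.append((u, v)); st.append(s); ins.append(a)
        if uv:
            branches.append({
                "uv": np.asarray(uv), "states": np.asarray(st),
                "inputs": np.asarray(ins), "branch_id": br.branch_id,
            })
    return PlanarCurve(pnc.module_id, u_label, v_label, branches)


# ---------------------------------------------------------------------------
# intersections


@dataclass
class Candidate:
    """A planar intersection (or grazing-contact) candidate."""

    u: float
    v: float
    grazing: bool
    # nearest branch points on each curve (for lifting to a full-state guess)
    state1: np.ndarray
    input1: float
    state2: np.ndarray
    input2: float


def _nearest_on(curve: PlanarCurve, pt: tuple[float, float]):
    best = None
    for br in curve.branches:
        d = np.hypot(br["uv"][:, 0] - pt[0], br["uv"][:, 1] - pt[1])
        i = int(np.argmin(d))
        if best is None or d[i] < best[0]:
            best = (float(d[i]), br["states"][i], float(br["inputs"][i]))
    return best


def find_intersections(c1: PlanarCurve, c2: PlanarCurve,
                       geom_tol: float = 1e-4) -> list[Candidate]:
    """All crossings of the two projected curves, plus grazing contacts.

    Crossings come from exact polyline segment intersection (shapely).  A
    *grazing* candidate is a locus where the curves approach within
    ``geom_tol`` without crossing — precisely the near-tangency geometry that
    precedes a saddle-node, so it is surfaced rather than discarded.
    """
    if c1.plane != c2.plane:
        raise ConfigurationError(f"curves live in different planes: {c1.plane} vs {c2.plane}")
    pts: list[tuple[float, float, bool]] = []
    lines1 = [LineString(br["uv"]) for br in c1.branches if len(br["uv"]) >= 2]
    lines2 = [LineString(br["uv"]) for br in c2.branches if len(br["uv"]) >= 2]
    if not lines1 or not lines2:
        raise ConfigurationError("both curves must be non-empty")
    for l1 in lines1:
        for l2 in lines2:
            inter = l1.intersection(l2)
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.is_empty:
                    continue
                if isinstance(g, Point):
                    pts.append((g.x, g.y, False))
                else:  # overlapping segment: take its midpoint
                    c = g.centroid
                    pts.append((c.x, c.y, False))
            if inter.is_empty:
                d = l1.distance(l2)
                if d <= geom_tol:
                    p1, _ = nearest_points(l1, l2)
                    pts.append((p1.x, p1.y, True))
    # local grazing contacts between crossing points are also of interest:
    # sample each l1 vertex's distance to l2 and keep isolated near-contacts
    for br in c1.branches:
        uv = br["uv"]
        if len(uv) < 3:
            continue
        d = np.array([min(l2.distance(Point(p)) for l2 in lines2) for p in uv])
        for i in range(1, len(uv) - 1):
            if d[i] <= geom_tol and d[i] <= d[i - 1] and d[i] <= d[i + 1]:
                pts.append((uv[i, 0], uv[i, 1], True))

    # dedupe, crossings take precedence over grazing flags
    pts.sort(key=lambda t: (t[2], t[0], t[1]))
    kept: list[tuple[float, float, bool]] = []
    for u, v, gr in pts:
        if any(abs(u - ku) <= geom_tol and abs(v - kv) <= geom_tol for ku, kv, _ in kept):
            continue
        kept.append((u, v, gr))

    out = []
    for u, v, gr in sorted(kept):
        n1 = _nearest_on(c1, (u, v))
        n2 = _nearest_on(c2, (u, v))
        out.append(Candidate(u, v, gr, n1[1], n1[2], n2[1], n2[2]))
    return out


# ---------------------------------------------------------------------------
# refinement and classification


STABILITY_LABELS = ("stable_node", "stable_focus", "saddle",
                    "unstable_node", "unstable_focus", "marginal")


def classify_eigenvalues(eigs: np.ndarray, marginal_tol: float = 1e-8) -> str:
    """Stability label from full-Jacobian eigenvalues.

    ``saddle`` requires a *real* positive eigenvalue together with stable
    directions; a complex pair with positive real part is an unstable focus
    (the post-Hopf geometry), regardless of additional stable directions.
    """
    re = eigs.real
    im = eigs.imag
    if np.any(np.abs(re) <= marginal_tol):
        return "marginal"
    unstable = re > 0
    if not unstable.any():
        return "stable_focus" if np.any(np.abs(im) > marginal_tol) else "stable_node"
    real_pos = unstable & (np.abs(im) <= marginal_tol)
    if real_pos.any() and (~unstable).any():
        return "saddle"
    if (~unstable).any():
        return "unstable_focus"
    return "unstable_focus" if np.any(np.abs(im) > marginal_tol) else "unstable_node"


@dataclass
class Intersection:
    """A refined steady state at a pseudo-nullcline intersection."""

    u: float
    v: float
    state: np.ndarray
    residual: float
    classification: str          # "transversal" | "tangential"
    stability: str
    eigenvalues: np.ndarray
    angle_deg: float | None = None   # diagnostic: angle between curve tangents
    converged: bool = True
    grazing: bool = False

    @property
    def lambda_min(self) -> float:
        return float(np.min(np.abs(self.eigenvalues)))


def _tangent_at(curve: PlanarCurve, pt: tuple[float, float]) -> np.ndarray | None:
    best, bt = np.inf, None
    for br in curve.branches:
        uv = br["uv"]
        if len(uv) < 2:
            continue
        d = np.hypot(uv[:, 0] - pt[0], uv[:, 1] - pt[1])
        i = int(np.argmin(d))
        if d[i] < best:
            j = min(i + 1, len(uv) - 1)
            k = max(i - 1, 0)
            t = uv[j] - uv[k]
            n = np.linalg.norm(t)
            if n > 0:
                best, bt = d[i], t / n
    return bt


def refine_and_classify(candidate: Candidate, system: CoupledSystem,
                        angle_tol: float = 5.0, root_tol: float = 1e-9,
                        sn_tol: float = 1e-5,
                        curves: tuple[PlanarCurve, PlanarCurve] | None = None,
                        projection: Callable | None = None) -> Intersection:
    """Newton-refine a planar candidate to a full steady state and classify it.

    The initial full-state guess stitches the module-1 state from the nearest
    C1 point with the module-2 state from the nearest C2 point.  The contact
    is *tangential* when the full Jacobian's smallest-magnitude eigenvalue is
    within ``sn_tol`` of zero (the limit-point statement); the angle between
    local curve tangents is reported as a diagnostic only.
    """
    guess = np.concatenate([candidate.state1, candidate.state2])
    sol = optimize.root(lambda s: system.full_rhs(s), guess, method="hybr",
                        options={"xtol": 1e-13})
    state = sol.x
    res = float(np.max(np.abs(system.full_rhs(state))))
    converged = bool(res <= root_tol and np.all(np.isfinite(state)))
    if not converged:
        state, res = guess, float(np.max(np.abs(system.full_rhs(guess))))
    J = full_jacobian(system, state)
    eigs = np.linalg.eigvals(J)

    angle = None
    if curves is not None:
        t1 = _tangent_at(curves[0], (candidate.u, candidate.v))
        t2 = _tangent_at(curves[1], (candidate.u, candidate.v))
        if t1 is not None and t2 is not None:
            c = float(np.clip(abs(np.dot(t1, t2)), 0.0, 1.0))
            angle = float(np.degrees(np.arccos(c)))

    lam_min = float(np.min(np.abs(eigs)))
    tangential = lam_min <= sn_tol
    if not tangential and angle is not None and angle <= angle_tol:
        logger.info("angle criterion suggests tangency (%.3g deg) but |lambda_min|=%.3g "
                    "exceeds sn_tol; eigenvalue criterion wins", angle, lam_min)

    u, v = candidate.u, candidate.v
    if converged and projection is not None:
        u, v = projection(state)

    return Intersection(
        u=float(u), v=float(v), state=state, residual=res,
        classification="tangential" if tangential else "transversal",
        stability=classify_eigenvalues(eigs),
        eigenvalues=eigs, angle_deg=angle, converged=converged,
        grazing=candidate.grazing,
    )


@dataclass(frozen=True)
class NullclineGeometry:
    """How to build the two projected curves for a system.

    Bundles the input ranges, trace configs and projections so curve-level
    analyses (intersection counting, tangency diagnostics) can be recomputed
    at any parameter value.  ``refine_projected`` iterations subdivide input
    intervals whose *projected* chord exceeds ``seg_frac`` of the plot
    diagonal, resolving near-vertical drops and hyperbolic sweeps where the
    raw input grid is too coarse.
    """

    range1: tuple[float, float]
    range2: tuple[float, float]
    config1: TraceConfig = TraceConfig()
    config2: TraceConfig = TraceConfig()
    transform1: Callable | None = None
    transform2: Callable | None = None
    labels: tuple[str, str] = ("u", "v")
    geom_tol: float = 1e-4
    refine_projected: int = 2
    seg_frac: float = 0.01

    def _one_curve(self, system: CoupledSystem, which: int) -> PlanarCurve:
        module = system.module1 if which == 1 else system.module2
        rng = self.range1 if which == 1 else self.range2
        cfg = self.config1 if which == 1 else self.config2
        tr = (self.transform1 if which == 1 else self.transform2) \
            or default_projection(system, which)
        grid = None
        curve = None
        cache: dict = {}
        for it in range(self.refine_projected + 1):
            pn = trace_pseudo_nullcline(module, rng, system.params, cfg,
                                        module_id=which, grid=grid, cache=cache)
            curve = project_curve(pn, tr, *self.labels)
            if it == self.refine_projected or not curve.branches:
                break
            all_uv = np.vstack([br["uv"] for br in curve.branches])
            diag = float(np.hypot(*np.ptp(all_uv, axis=0))) or 1.0
            extra = []
            for br in curve.branches:
                uv, ins = br["uv"], br["inputs"]
                seg = np.hypot(*np.diff(uv, axis=0).T)
                for j in np.nonzero(seg > self.seg_frac * diag)[0]:
                    extra.append(0.5 * (ins[j] + ins[j + 1]))
            if not extra:
                break
            base = grid if grid is not None else cfg.make_grid(*rng)
            grid = sorted(set(float(g) for g in list(base) + extra))
        return curve

    def curves(self, system: CoupledSystem) -> tuple[PlanarCurve, PlanarCurve]:
        return self._one_curve(system, 1), self._one_curve(system, 2)


def intersections_of(system: CoupledSystem, geometry: NullclineGeometry,
                     include_grazing: bool = False,
                     only_converged: bool = True,
                     root_tol: float = 1e-9, sn_tol: float = 1e-5) -> list[Intersection]:
    """End-to-end pipeline: trace both pseudo-nullclines, project, intersect,
    refine, classify, dedupe.

    Spurious repeated crossings (polyline noise where the curves run nearly
    coincident) collapse onto the same refined root; candidates whose Newton
    refinement fails are dropped unless ``only_converged=False``, in which
    case they are returned with ``converged=False``.
    """
    c1, c2 = geometry.curves(system)
    cands = find_intersections(c1, c2, geometry.geom_tol)
    uniq: list[Intersection] = []
    for cd in cands:
        if cd.grazing and not include_grazing:
            continue
        it = refine_and_classify(cd, system, root_tol=root_tol, sn_tol=sn_tol,
                                 curves=(c1, c2))
        if not it.converged and only_converged:
            continue
        if it.converged and any(u.converged and np.max(np.abs(u.state - it.state)) < 1e-6
                                for u in uniq):
            continue
        uniq.append(it)
    return uniq
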