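# Methods

## The pseudo-nullcline construction

Many signaling models of dimension n > 2 decompose into two *modules* — blocks
of state variables `x` and `y` that sense each other only through one scalar
each:

    dx/dt = f(x, α(y)),      dy/dt = g(y, β(x)).

Freezing a module's scalar input `a` turns it into an input/output system
whose steady states `x = X(a)` can be traced numerically.  Projecting the two
solution sets onto the plane of the coupling scalars `(β(x), α(y))` gives two
curves, C1 and C2, that behave like nullclines of a planar system:

* every steady state of the coupled system lies on an intersection of C1 and
  C2 (the converse needs the full-state refinement — a planar crossing may
  combine incompatible sheets, which is why every candidate is polished by a
  full-dimensional Newton solve and kept only if it converges);
* a **transversal** crossing is an ordinary fixed point; stability comes from
  the full Jacobian, not the plane;
* a **tangential** contact marks a limit point: two steady states coalescing,
  i.e. a saddle-node (fold).  Operationally, tangency is declared from the
  full Jacobian (smallest-magnitude eigenvalue within `sn_tol = 1e-5` of
  zero); the angle between the local curve tangents is reported as a
  diagnostic only, because the projection can make genuinely transversal
  manifolds look locally parallel (the two criteria disagree exactly in
  strongly sheared planes).

### Branch tracing

Curves are traced by *per-input multi-start root sweeps* linked by nearest
neighbour — not by arclength continuation.  At every grid value of the input,
all module steady states are found (deterministic Halton starts over the
admissible box, a bounded least-squares pass seeded at the box corners for
roots pressed against the boundary, plus warm starts from the previous grid
value); folded, S-shaped solution sets therefore come out as separate sheets
without fold handling, and disconnected branches cannot be lost by a
continuation step jumping across.  Grid intervals where the root count
changes are bisected (`max_refine = 8` levels) so fold edges are sharp, and
input intervals whose *projected* chord is long (more than `seg_frac = 1%` of
the plot diagonal, `refine_projected = 2` rounds) get midpoint samples — this
is what resolves near-vertical drops and hyperbolic sweeps of the curves.

Grids are linear by default; modules whose response sweeps like `1/input`
(the Cdk1 module against APC activity, the level-2 MAPK module against its
load) use log-spaced grids.  There is no random number generator anywhere in
the pipeline: repeated runs are byte-identical.

Key tolerances: root residual `root_tol = 1e-9` (max-norm), deduplication
`dedupe_tol = 1e-6` (max-norm on states), planar intersection/grazing
tolerance `geom_tol` (1e-4 in plot units; 1e-3 for the cell-cycle plane whose
axes span hundreds of nM).  Grazing contacts — curves approaching within
`geom_tol` without crossing — are reported with a flag rather than dropped,
since near-tangency is the method's key signal.

### Tangency gap

A scalar diagnostic of closeness-to-tangency computed from the curves alone:
for each point of C1, its perpendicular distance to C2 (normalized by the
plot diagonal) plus the tangent misalignment `1 − |cos θ|` at the nearest C2
segment; the gap is the minimum of that sum.  It is zero exactly at a
tangential contact, stays positive at transversal crossings (the alignment
term) and for separated curves (the distance term), and its minima over a
parameter scan land on the folds.

## Bifurcation detection

Detection is sweep + bisection on root topology and eigenvalues; no
continuation package is used or replicated:

* **Saddle-node** — the number of steady states changes between adjacent scan
  values; bisected to `1e-7` in the parameter, then polished by Newton on the
  extended system (RHS = 0 together with the smallest-magnitude eigenvalue
  = 0), after which `|λ_min| ≤ 1e-5` is verified at the fold state.
* **Hopf** — the real part of a complex-conjugate eigenvalue pair changes
  sign along a linked branch; bisected to `1e-7` with Newton continuation of
  the state (hybr with a Levenberg–Marquardt fallback on stiff systems).
  The pair is followed by eigenvalue continuity, since it can transiently
  collide on the real axis inside the bracket; when the crossing happens in
  such a degenerate stretch the event is still reported but its
  `re_ok` diagnostic is false — the location is then only grid-accurate.
  Real-eigenvalue sign changes are excluded (those are folds).
* **Infinite-period onset (SHom / SNIC)** — bisection on limit-cycle
  existence inside a bracket with one oscillatory end, stretching the
  integration horizon (×4, up to 3 times, sampling density held constant)
  whenever the cycle test is inconclusive, and monitoring the period.  The
  label is `SNIC_candidate` when the located parameter coincides (1e-3) with
  a known fold or no saddle exists there, `SHom_candidate` when a separate
  saddle is involved.  These are candidates, not certificates: the period
  scaling law (logarithmic for homoclinic, inverse square root for SNIC) and
  the saddle eigenvalues settle the distinction.

Steady-state candidates during scans come from the pseudo-nullcline pipeline
at grid values and from warm-started Newton polishing at bisection midpoints
(re-tracing curves thousands of times inside a bisection would be wasteful,
and warm roots are within Newton's basin; a vanished fold pair cannot be
re-invented by polishing, so root counts stay honest).

## Dynamics

Trajectories use stiff-capable SciPy solvers (LSODA, `rtol 1e-8`,
`atol 1e-10`) with uniform dense output (4000 samples by default).  Limit
cycles are declared from at least four post-transient peaks (local maxima
with quadratic interpolation of peak times) whose spacing and height agree to
1%; quiescence needs the post-transient range to fall below `1e-3` of the
variable scale; anything else is flagged inconclusive rather than forced into
a boolean.  The transient discard is amplitude-based (first half of the
record, extended when peaks have not settled) because near-homoclinic cycles
have extreme periods.  Excitability probes classify an initial condition as a
*large excursion* when the trajectory wanders more than 5× its initial
displacement from the stable state before converging there, and as a *direct
return* otherwise.  "Above/below the saddle" is operationalized as a
displacement along the projected vertical coordinate from the saddle state.

## Case studies

### Embryonic cell-cycle oscillator

Four variables in two modules: active/inactive Cdk1–cyclin (module 1) and
active Plx1/APC fractions (module 2), couplings α(y) = apca, β(x) = cdk1a.
Cyclin synthesis (`k_synth`, nM/min) feeds active complexes; Cdc25 and Wee1
interconvert them with Hill feedbacks on Cdk1 activity whose amplitudes scale
with the positive-feedback strength `r`; degradation of both forms is purely
APC-mediated (`k_dest · apca`).  Plx1 is activated by Cdk1a and APC by Plx1
(Hill); `extra` adds a Plx1-independent basal APC activation route (0 by
default).  The plotting plane is (Cyc_tot, Cdk1a) with Cyc_tot = cdk1a +
cdk1i; along the APC curve, cdk1i is recovered from the Cdk1 module's own
balance at the curve's (cdk1a, apca) — the only self-consistent choice given
that module 2 does not carry cdk1i.

The shipped parameter set reconstructs the published *X. laevis* embryonic
oscillator phenotype rather than any single printed table: with `r = 0.5`
the lower Hopf sits at k_synth ≈ 0.048 (stable spiral at 0.04, small cycle at
0.05), the relaxation cycle at 1.5 rides the lower sheet of the Cdk1 curve,
and the upper Hopf lies between 3 and 5.  The package's *modified regime*
(`r = 10`, `ec50_plx = 72`, `extra = 6.5e-3`) pulls the APC curve down onto
the Cdk1 curve's right-hand fold: a saddle-node pair at k_synth ≈ 0.57 and
≈ 1.63 brackets an excitable window (containing 1.52) where a stable arrest
state coexists with a threshold saddle, and the oscillation above the upper
fold is born with diverging period — the fold sits on the cycle.  The value
of `extra` was chosen just above the tangency onset so the arrest window
appears without destroying the surrounding oscillation; much larger values
tip the model into plain bistability.

### The 2+2 MAPK motif

The last two levels of a MAPK cascade: kinase K (K0/K1/K2) phosphorylated
distributively by the input kinase E1 and reversed by phosphatase P2; free K2
phosphorylates the level-3 substrate A (A/Ap/App), reversed by P3.
Seventeen mass-action species; five conservation laws.  Three views:

* the raw 17-ODE network (trajectories, conservation checks);
* the same network in 12 reduced coordinates (conservations eliminated), so
  steady states are isolated and E1tot is a genuine scan parameter;
* a 4-variable two-module reduction: state (K0, X | A, App), where X = K2 +
  AK + ApK is the total doubly-phosphorylated kinase and the level-3
  variables are *pool totals* (free + complex-bound per modification state).
  Enzymes follow Michaelis–Menten with competing substrates; kinase–substrate
  complexes follow rapid-equilibrium occupancy.  Free amounts are recovered
  from the pools at every RHS evaluation by implicit conservation solves
  (bracketed warm-started Newton for K1; a damped fixed-point contraction for
  the level-3 frees).  The module-2 → module-1 coupling scalar is the load
  Z = c1·A_free + c2·Ap_free (c are reciprocal Michaelis constants of the
  K2–substrate binding steps); because the frees depend on how much K2 is
  around to bind, α is evaluated as α(y, β(x)) — the coupling remains one
  scalar in each direction, with the wiring allowed to pass the other
  scalar through.  With this bookkeeping the reduction's steady states agree
  with the full network's to ~1e-5 relative and oscillation periods to ~7%.

There is no explicit feedback loop in the motif: the oscillation is
sequestration-driven.  Substrate-bound K2 is invisible to P2, so a loaded
level 2 accumulates X; conversion of the substrate to App dissolves the load,
exposes K2 to its phosphatase, and X collapses — a delayed negative feedback.
Both modules are bistable against their own inputs (level 2 against the load,
level 3 against X), the property the motif's source parameterization is
stated to have.  The shipped rate constants were selected by a deterministic
(Halton) screen of the kinetic space for exactly these properties — module
bistability plus a Hopf-bounded oscillation window of the coupled system
inside the E1tot scan range — and then rounded; the defaults place the window
at E1tot ≈ (0.22, 0.31) with the output off most of each period (duty
fraction < 0.5).  In this parameterization the coupled system keeps a single
steady state across the scan window, so the window is bounded by two Hopf
bifurcations rather than by folds; the fold/tangency machinery is therefore
demonstrated on the modified cell cycle, where the geometry produces it.

## What the bundled models do and do not show

The toys (FitzHugh–Nagumo split into its two variables, a coupled linear
pair, fold and Hopf normal forms embedded as two-module systems) carry the
analytic oracles: pseudo-nullclines equal true nullclines in the degenerate
1-D + 1-D case, fixed points equal linear solves, detected events land on the
normal forms' known parameters.  The case studies exercise the method on
stiff, folded, multistable chemistry.  None of this certifies behaviour of
the models outside the scanned windows, and the case-study parameter sets are
reconstructions (see the repository history notes): they reproduce the
documented qualitative structure — onset positions, fold/excitability
geometry, duty-cycle asymmetry — not any particular published decimal.

## Numerical choices and limitations

* State ordering is fixed (module 1 then module 2); all projections derive
  from it.
* Model equations are evaluated as written — no clipping; admissibility
  (non-negativity, conservation simplexes) is enforced by filtering roots and
  by error margins (1e-6 of scale) around the feasible set, not by altering
  the vector field.
* Jacobians are scale-aware central differences (step `1e-6·max(1, |x|)`)
  unless a model registers an exact form.
* The coupling closures capture their parameter set at construction; scans
  vary a single named parameter that must not enter the coupling constants
  (true for both case studies).  Overrides that do affect them must go
  through the model factories.
* Stability labels at an exact bifurcation are `marginal` by construction;
  classification within `1e-8` of the imaginary axis is not meaningful.
* The tangency gap is a diagnostic, not a certified distance: in strongly
  sheared projections its absolute scale is plane-dependent, so only
  contrasts (near-fold vs off-fold, tangential vs transversal regime) are
  interpreted.
* Multistability can hide from any finite multi-start sweep; the pipeline's
  completeness checks are against a 400-start brute-force sweep, itself not a
  proof.
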