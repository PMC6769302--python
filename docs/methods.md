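# Methods

## Model

The presomitic mesoderm (PSM) is a line of phase oscillators on the scaled
axis x ∈ [0, 1], posterior tip at x = 0, anterior front at x = 1. A cell at
position x advances its segmentation-clock phase at dφ/dt = 2π/T(x), with
the period gradient

    T(x) = T0 (1 + ξ + λ x),

T0 the posterior period (130 min in mouse), λ the slope (0.266 in mouse)
and ξ an optional uniform additive perturbation in units of T0. Arbitrary
monotone gradients are supported as tabulated samples joined piecewise
linearly; all theory below needs only that T is non-decreasing.

Two tissue-dynamics regimes are modelled:

- **Constant length.** Cells are added at the posterior (each copying the
  posterior boundary phase) and a somite — the anterior-most block spanning
  a fraction β of the post-formation length — is removed every Ts minutes.
  Growth balances removal, so the scaled description is stationary.
- **No growth.** Cell addition has stopped (end of somitogenesis); a somite
  is removed whenever the posterior-to-anterior phase difference reaches a
  threshold Φ_before, cutting the anterior cells that span φ~ of phase. The
  PSM shrinks with every somite.

### Steady-state constraint

In either steady state the total phase difference Δφ(t) = φ(0) − φ(1)
grows linearly between formations at rate 2πλ/(T0(1+λ)) (for the linear
gradient) and drops by the somite's phase width φ~ at each formation.
Periodicity with k full waves across the PSM (Φ_before = 2πk) and one
formation per posterior period (Ts = T0) force

    φ~ = 2π k λ / (1 + λ),

which is 0.2101·2π for the mouse values — the closed form implemented in
`psmclock.constraints`. A uniform perturbation ξ generalizes this to
φ~(ξ) = 2πkλ/(1+λ+ξ): lengthening all periods uniformly dilutes the
relative gradient and shrinks somites. For general Ts the same bookkeeping
gives φ~ = 2π(Ts/T0)·λ/(1+λ).

## Discrete simulator

`psmclock.discrete_sim` is event-driven and exact. N cells sit at
x_i = i/(N−1); between events positions are fixed, so each phase advances
by exactly 2π·dt/T(x_i) — there is no integration error, and the threshold
crossing time is solved in closed form from the constant growth rate
2π/T(0) − 2π/T(1) of Δφ. Growth events copy the posterior phase into a new
cell; formation events remove an anterior block (Ts/Tg cells under the
timed rule, with floor/ceiling alternation and an exact debt account when
the ratio is not an integer; the smallest suffix spanning at least φ~ under
the threshold rule). Coincident events are ordered growth → formation →
snapshot. Steady states are detected on the lag profile ψ(x) = φ(0) − φ(x),
which is free of the mod-2π ambiguity, compared in sup norm on a fixed
201-point grid across successive post-formation snapshots.

In the constant-length regime the steady state is reached *exactly* once
every initial cell has been flushed through the tissue (about 1/β + 1
cycles), because newly added cells are born into the steady-state rule; the
converged profile is therefore independent of the initial condition,
including random ones.

## Constant-length continuum solution

A material point keeps its physical distance a from the anterior front
while the tissue length grows as L(t) = 1 + βt/Ts within a cycle, so its
scaled position follows x(t) = 1 − a/L(t). Its phase gain over part of a
cycle is G(a) = ∫ 2π/T(x(t)) dt. Substituting u = L(t) turns the integrand
over an affine segment T = A + Bx into u/(pu − q) with p = A + B, q = Ba,
which integrates to u/p + (q/p²) ln(pu − q). The gain is therefore
available in closed form for both gradient kinds — piecewise-affine
tabulated gradients included, with knot-crossing times solved explicitly —
and the package uses these closed forms instead of numerical quadrature:
they are exact to rounding and kink-exact, which matters for the
second-difference shape tests below.

The steady post-formation lag profile is built directly, without
iteration. Cells in the posterior segment x ∈ [0, β] were added during the
last cycle at a birth time known from their position; their lag follows
from the birth trajectory. Every other point maps back one cycle by
ψ(x) = ψ(x − β) + 2πTs/T(0) − G(1 − x + β). The construction is validated
internally: re-propagating the post-formation profile through one cycle and
removing the somite reproduces it with a sup-norm residual at rounding
level (≈ 1e-14), and the emergent phase width matches the closed-form
constraint to machine precision.

### Concavity and its oracle

For any increasing gradient the constant-length profile is concave in x:
two nearby material points drift anteriorward together, and the phase
difference between them grows because the trailing point always sits on the
faster (more posterior) side. `diagnostics.concavity_oracle_increment`
checks this numerically two ways — the exact difference of the two
trajectory gains, and its first-order expansion
ε ∫ 2π T′(x(t))/T(x(t))² · dt/L(t) along one trajectory (midpoint rule,
32768 points, so slope discontinuities of tabulated gradients stay well
below the O(ε²) agreement being tested) — and reports the steepening ratio,
which exceeds 1 whenever the gradient increases and equals 1 exactly when
it is flat.

Concavity makes the kinematic waves decelerate as they approach the
anterior, and it steepens the anterior profile, which damps the effect of
phase-measurement errors on somite width (`width_error_sensitivity`).

## No-growth fixed point

With positions fixed, the lag profile grows pointwise at
2π/T(0) − 2π/T(x) until Δφ reaches Φ_before; the somite spanning φ~ is cut
at the position x_c where the remaining span equals Φ_before − φ~, and the
surviving profile is rescaled to [0, 1]. The steady state is the fixed
point of this evolve–cut–rescale map, found by iteration from a linear
profile (monotone-cubic interpolation for the rescale, Brent root-finding
for the cut; sup-norm tolerance 1e-10, typically a few dozen iterations).
The PSM shrinks by the constant factor x_c per somite — exponential decay
of PSM length. At the mouse values (Φ_before = 2π, φ~ = 0.21·2π) the fixed
point gives x_c = 0.76761 and an emergent formation period of 129.93 min;
a first-order estimate ignoring the profile's curvature gives ≈ 0.79, and
the discrete simulator matches the exact value within 1% at N ≈ 500 and
within 0.1% at very large N.

### Shape dichotomy and its limits

For the linear gradient the no-growth fixed point is slightly *convex*
(chord deviation ≈ 2.6% of the span at the mouse values) — opposite in
curvature to the constant-length profile. The package's tests treat
"near-linear" as a chord deviation below 5% of the span.

The convex side of the dichotomy is, however, not gradient-independent.
For the monotone quadratic gradient T(x) = 130(1 + 0.266x²) the no-growth
fixed point is genuinely concave (chord deviation ≈ +0.18·2π on the concave
side): without growth the profile shape follows the gradient's own
curvature, and only the constant-length concavity argument above holds for
every increasing gradient. This was cross-validated with the discrete
simulator at N = 20000, which reproduces the continuum fixed point to 1e-3
in sup norm and the same shrink factor (0.876) to four digits. The
acceptance test asserts this actual behavior: concavity in the
constant-length regime for both gradient kinds, convexity and
near-linearity without growth for the linear gradient, and the concave-side
chord deviation without growth for the quadratic gradient.

A further numerical point: piecewise-linear tabulated gradients inject
curvature spikes of order 1e-5 at their knots into no-growth profiles
(in the constant-length regime the kinks only reinforce concavity), so
no-growth shape statements for tabulated gradients use the chord-deviation
criterion rather than pointwise second differences at 1e-8 slack.

## Defaults and problem sizes

The study conditions are mouse: T0 = 130 min, λ = 0.266, k = 1, Ts = T0,
β = 1/7 (N = 70 with sawtooth growth of 10 cells per cycle), and
Φ_before = 2π, φ~ = 0.21·2π for the no-growth endgame. Continuum grids are
201 points (constant length; the profile there is exact pointwise, the grid
only sets the output resolution) and 1001 points (no-growth map, where the
grid does discretize the fixed point). Scaling comparisons use N = 7, 14,
70; the shrinkage test uses a 10-somite run from N = 3000; the perturbation
sweeps use ξ ∈ [−0.2, 0.5]. Sup-norm profile distances are reported as
fractions of 2π, the package-wide phase reporting unit.

## Limitations

- Oscillators are uncoupled phase variables: no phase coupling between
  neighbours, no amplitude dynamics, no noise. The model addresses the
  geometry of the steady phase pattern, not synchronization.
- Positions are prescribed (uniform growth, scaled coordinates), not
  mechanically derived; cell mixing and local growth profiles are outside
  scope.
- The timed formation rule requires a growth interval Tg (its removal count
  is Ts/Tg); a non-growing PSM must use the threshold rule.
- The no-growth fixed point describes the self-similar regime while enough
  cells remain; the final somites of a real embryo, where N is small, show
  the discretization effects the scaling analysis quantifies.
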