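# psmclock

A phase-oscillator model of somite formation in the presomitic mesoderm
(PSM), the unsegmented posterior tissue of vertebrate embryos from which
somites — the precursors of vertebrae — are cut off periodically.

The PSM is modelled as a one-dimensional line of oscillators on the scaled
axis x ∈ [0, 1] (x = 0 posterior tip, x = 1 anterior front). Each cell runs
the segmentation clock, a gene-expression oscillation represented by a
single phase, with a period that lengthens from posterior to anterior,

    T(x) = T0 (1 + ξ + λ x)

(mouse values T0 = 130 min, λ = 0.266; ξ is an optional uniform period
perturbation). The period gradient makes posterior cells overtake anterior
ones in phase, which produces the kinematic waves seen sweeping anteriorward
across the PSM, and — together with posterior growth and periodic anterior
removal — determines the phase span φ~ of each somite, the formation period
Ts and the shape of the steady-state phase profile.

## What the package computes

- **Closed-form steady-state constraints** linking the gradient slope λ,
  the somite phase width φ~, the number of waves k spanning the PSM and the
  formation period: φ~ = 2πkλ/(1+λ), its inverse, the uniform-perturbation
  generalization φ~(ξ) = 2πkλ/(1+λ+ξ), and the linear growth of the total
  phase difference between formations.
- **An exact event-driven discrete simulator** of N cells with posterior
  growth (new cells copy the posterior phase) and two somite-formation
  rules: *timed* (a somite forms every Ts minutes) or *threshold* (a somite
  forms when the posterior-to-anterior phase difference reaches Φ_before).
  Phase updates between events are exact; no ODE stepping error.
- **Continuum steady-state solvers**: the constant-length regime (growth
  balances removal) by direct construction along material-point
  characteristics with closed-form phase-gain integrals, and the no-growth
  end-of-somitogenesis regime as the fixed point of an evolve–cut–rescale
  map, where the PSM shrinks by a constant factor per somite.
- **Diagnostics**: profile curvature classification (the concave/convex
  dichotomy between the two regimes), a numerical oracle for the concavity
  argument, Φ_before heatmaps over (λ, β), kinematic-wave tracking,
  somite-width sensitivity to phase-measurement errors, and dynamical
  scaling of discrete profiles toward the continuum limit.

## Quick start (library)

```python
import psmclock as pc

# closed-form constraint: slope 0.266 <-> phase width 0.21 * 2pi
pc.phase_width_from_lambda(0.266, k=1)     # 0.21011...
pc.lambda_from_phase_width(0.21, k=1)      # 0.26582...

# discrete steady state, mouse conditions: N = 70, one formation per T0,
# sawtooth growth of 10 cells per cycle
clock = pc.ClockParams(t0=130.0, lam=0.266)
regime = pc.RegimeParams(rule="timed", ts=130.0, tg=13.0, n=70, beta=1/7)
res = pc.run_to_steady_state(clock, regime)
res.phi_width_frac        # 0.210110... (emergent, matches the constraint)
res.ts                    # 130.0 min

# continuum limit of the same regime
cont = pc.steady_profile_constant_length(clock, beta=1/7)
cont.phi_width_frac       # 0.210110... to machine precision

# end of somitogenesis: no growth, threshold rule
import math
ng = pc.steady_profile_no_growth(clock, phi_before=2*math.pi,
                                 phi_width=0.21*2*math.pi)
ng.shrink_factor          # 0.76761 — PSM length ratio per somite
ng.ts                     # 129.93 min — emergent formation period
```

## Quick start (CLI)

```sh
psmclock constraint --lambda 0.275 --k 1     # phi_width_frac: 0.2157
psmclock simulate --n 70 --tg 13 --ts 130 --out run/
psmclock steady-state --beta 0.142857 --out cont/
psmclock no-growth --phi-before 1.0 --phi-width 0.21 --out ng/
psmclock heatmap --steps 10 --out heatmap.csv
psmclock perturb --xi-min -0.2 --xi-max 0.5 --out perturb.csv
psmclock waves --n 200 --out waves.csv
psmclock fixtures --out scenarios/           # built-in scenario YAMLs
```

Phase quantities on the command line and in config files are fractions of
2π; times are minutes. Every command is deterministic for a fixed
configuration and seed, and CSV/JSON outputs are byte-identical across
repeated runs.

## Layout

| module | contents |
| --- | --- |
| `psmclock.gradients` | `ClockParams`, linear and tabulated period gradients |
| `psmclock.constraints` | closed-form steady-state algebra, `RegimeParams` |
| `psmclock.discrete_sim` | event-driven N-cell simulator, steady-state driver |
| `psmclock.continuum` | constant-length and no-growth steady-state solvers |
| `psmclock.diagnostics` | concavity, oracle, heatmap, waves, sensitivity, scaling |
| `psmclock.config` / `io` / `cli` | scenario schema, deterministic writers, `psmclock` CLI |

`docs/methods.md` describes the model, the solvers and the numerical
choices in detail.
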