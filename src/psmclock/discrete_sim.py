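"""Event-driven simulator of the finite-N oscillator line.

The PSM is a line of N cells, posterior (index 0, x = 0) to anterior
(index N−1, x = 1), with scaled positions x_i = i/(N−1).  Each cell advances
its phase at 2π/T(x_i); between events positions are constant, so the phase
update is exact (no ODE stepping error).  Growth events copy the posterior
phase into a new posterior cell every Tg minutes; formation events remove an
anterior block of cells, either on a timer (every Ts, removing the Ts/Tg
cells added since the previous formation) or when the posterior-to-anterior
phase difference reaches a threshold Φ_before (removing the smallest anterior
suffix spanning at least φ~ of phase).  Coincident events are ordered
growth → formation → snapshot.

Phases are stored unwrapped; steady states are detected on the lag profile
ψ(x) = φ(0) − φ(x), which is insensitive to the mod-2π freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constraints import RegimeParams
from .errors import (
    ConvergenceError,
    ExhaustionError,
    ParameterError,
    StagnationError,
)
from .gradients import ClockParams, PeriodGradient, linear_gradient
from .profiles import PhaseProfile, SteadyStateResult

TWO_PI = 2.0 * math.pi

__all__ = [
    "PSMState",
    "SomiteRecord",
    "SimulationResult",
    "init_state",
    "step",
    "add_posterior_cell",
    "form_somite",
    "run",
    "run_to_steady_state",
]


@dataclass(frozen=True)
class PSMState:
    """The oscillator line at one instant.

    ``phases`` is ordered posterior→anterior and unwrapped (cumulative
    radians).  ``events`` accumulates ``(time, kind, detail)`` tuples for
    additions and removals.
    """

    time: float
    phases: np.ndarray
    gradient: PeriodGradient
    events: tuple = ()

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        if phases.ndim != 1 or phases.size < 2:
            raise ParameterError("PSM needs at least 2 cells")
        if not np.all(np.isfinite(phases)):
            raise ParameterError("phases must be finite")
        object.__setattr__(self, "phases", phases)

    @property
    def n(self) -> int:
        return int(self.phases.size)

    @property
    def x(self) -> np.ndarray:
        """Scaled positions x_i = i/(N−1), posterior first."""
        return np.linspace(0.0, 1.0, self.n)

    @property
    def delta_phi(self) -> float:
        """Posterior-to-anterior phase difference φ(0) − φ(N−1), radians."""
        return float(self.phases[0] - self.phases[-1])

    def lag_profile(self, stage: str = "post") -> PhaseProfile:
        return PhaseProfile(x=self.x, phi=self.phases.copy(), stage=stage, n_cells=self.n)


@dataclass(frozen=True)
class SomiteRecord:
    """Bookkeeping for one somite-formation event."""

    index: int
    time: float
    cells_removed: int
    phase_span: float  # φ(boundary survivor) − φ(anterior-most), radians
    beta: float  # cells_removed / post-formation N
    len_before: int
    len_after: int


@dataclass(frozen=True)
class SimulationResult:
    state: PSMState
    somites: tuple[SomiteRecord, ...]
    snapshots: tuple[tuple[float, PhaseProfile], ...] = ()


def init_state(
    n: int,
    gradient: ClockParams | PeriodGradient,
    initial_profile="synchronized",
    seed: int | None = None,
) -> PSMState:
    """Create a PSM of ``n`` cells at time 0.

    ``initial_profile`` is ``"synchronized"`` (all phases 0), a
    ``("linear", span)`` pair giving phases decreasing linearly from ``span``
    at the posterior to 0 at the anterior, ``"random"`` (uniform on [0, 2π),
    requires ``seed``), or an explicit sequence of length ``n``.
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    grad = linear_gradient(gradient) if isinstance(gradient, ClockParams) else gradient
    if isinstance(initial_profile, str) and initial_profile == "synchronized":
        phases = np.zeros(n)
    elif isinstance(initial_profile, str) and initial_profile == "random":
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0.0, TWO_PI, size=n)
    elif (
        isinstance(initial_profile, tuple)
        and len(initial_profile) == 2
        and initial_profile[0] == "linear"
    ):
        span = float(initial_profile[1])
        phases = np.linspace(span, 0.0, n)
    else:
        phases = np.asarray(initial_profile, dtype=float)
        if phases.shape != (n,):
            raise ParameterError(
                f"user-supplied profile has length {phases.size}, expected {n}"
            )
    return PSMState(time=0.0, phases=phases, gradient=grad)


def step(state: PSMState, dt: float) -> PSMState:
    """Advance every phase by 2π·dt/T(x_i); exact for fixed positions."""
    if not dt > 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    phases = state.phases + TWO_PI * dt / state.gradient(state.x)
    return replace(state, time=state.time + dt, phases=phases)


def add_posterior_cell(state: PSMState) -> PSMState:
    """Append a posterior cell copying the current posterior phase."""
    phases = np.concatenate(([state.phases[0]], state.phases))
    events = state.events + ((state.time, "growth", 1),)
    return replace(state, phases=phases, events=events)


def _removal_count_threshold(state: PSMState, phi_width: float) -> int:
    span_if_boundary = state.phases - state.phases[-1]
    eligible = np.nonzero(span_if_boundary >= phi_width - 1e-12)[0]
    if eligible.size == 0:
        raise ParameterError(
            f"phase width {phi_width:g} exceeds the span of the profile "
            f"({span_if_boundary[0]:g})"
        )
    boundary = int(eligible[-1])  # largest index => smallest suffix
    return state.n - 1 - boundary


def form_somite(
    state: PSMState,
    regime: RegimeParams,
    index: int = 0,
    removal_count: int | None = None,
) -> tuple[PSMState, SomiteRecord]:
    """Cut a somite from the anterior end.

    Timed rule: remove ``removal_count`` cells (the driver supplies Ts/Tg,
    alternating floor/ceil when the ratio is not an integer).  Threshold
    rule: remove the smallest anterior suffix whose phase span is at least
    φ~ (overshoot allowed; cells are atomic).
    """
    if regime.rule == "threshold":
        r = _removal_count_threshold(state, regime.phi_width)
    else:
        if removal_count is None:
            ratio = regime.ts / regime.tg
            removal_count = int(round(ratio))
        r = removal_count
    if r < 1:
        raise ParameterError("somite must remove at least one cell")
    if state.n - r < 2:
        raise ExhaustionError(
            f"removing {r} of {state.n} cells would leave fewer than 2"
        )
    boundary = state.n - 1 - r
    span = float(state.phases[boundary] - state.phases[-1])
    record = SomiteRecord(
        index=index,
        time=state.time,
        cells_removed=r,
        phase_span=span,
        beta=r / (state.n - r),
        len_before=state.n,
        len_after=state.n - r,
    )
    new = replace(
        state,
        phases=state.phases[: boundary + 1].copy(),
        events=state.events + ((state.time, "formation", r),),
    )
    return new, record


def _threshold_rate(state: PSMState) -> float:
    """Growth rate of Δφ at the current positions, rad/min."""
    g = state.gradient
    return TWO_PI / g(0.0) - TWO_PI / g(1.0)


def run(
    clock: ClockParams | PeriodGradient,
    regime: RegimeParams,
    n: int | None = None,
    n_formations: int | None = None,
    horizon: float | None = None,
    initial_profile="synchronized",
    seed: int | None = None,
    sample_every: float | None = None,
    snapshot_formations: bool = True,
) -> SimulationResult:
    """Run the event-driven evolution.

    Stops after ``n_formations`` somites or at time ``horizon``, whichever
    comes first (at least one must be given).  Snapshots are taken just
    before and just after each formation (and, if ``sample_every`` is set, on
    a regular clock as well).  Coincident events run growth first, then
    formation.
    """
    if n_formations is None and horizon is None:
        raise ParameterError("give n_formations and/or horizon")
    n0 = n if n is not None else regime.n
    if n0 is None:
        raise ParameterError("initial cell count n is required")
    grad = linear_gradient(clock) if isinstance(clock, ClockParams) else clock
    state = init_state(n0, grad, initial_profile, seed=seed)

    timed = regime.rule == "timed"
    if timed:
        ratio = regime.ts / regime.tg
        if not math.isclose(ratio, round(ratio), rel_tol=0, abs_tol=1e-9):
            warnings.warn(
                f"ts/tg = {ratio:g} is not an integer; removal counts will "
                "alternate between floor and ceiling",
                stacklevel=2,
            )
    elif _threshold_rate(state) <= 0:
        raise StagnationError(
            "flat gradient: Δφ cannot grow, the threshold rule never fires"
        )

    somites: list[SomiteRecord] = []
    snapshots: list[tuple[float, PhaseProfile]] = []
    added_since_formation = 0
    removed_fractional_debt = 0.0
    next_growth = regime.tg if regime.grows else math.inf
    next_sample = sample_every if sample_every else math.inf
    eps = 1e-9

    def advance_to(t: float) -> None:
        nonlocal state
        if t > state.time + eps:
            state = step(state, t - state.time)
        else:
            state = replace(state, time=t)

    while True:
        if timed:
            next_formation = (len(somites) + 1) * regime.ts
        else:
            rate = _threshold_rate(state)
            gap = regime.phi_before - state.delta_phi
            next_formation = state.time + max(gap, 0.0) / rate if gap > 0 else state.time

        t_next = min(next_growth, next_formation, next_sample)
        if horizon is not None and t_next > horizon + eps:
            advance_to(horizon)
            if not timed and not somites:
                raise StagnationError(
                    f"threshold rule did not fire within horizon {horizon:g} min"
                )
            break

        advance_to(t_next)

        if next_growth <= t_next + eps:
            state = add_posterior_cell(state)
            added_since_formation += 1
            next_growth += regime.tg

        if next_formation <= t_next + eps:
            if snapshot_formations:
                snapshots.append((state.time, state.lag_profile(stage="pre")))
            if timed:
                exact = regime.ts / regime.tg + removed_fractional_debt
                r = int(math.floor(exact + 1e-9))
                removed_fractional_debt = exact - r
            else:
                r = None
            state, record = form_somite(
                state, regime, index=len(somites), removal_count=r
            )
            somites.append(record)
            if snapshot_formations:
                snapshots.append((state.time, state.lag_profile(stage="post")))
            added_since_formation = 0
            if n_formations is not None and len(somites) >= n_formations:
                break

        if next_sample <= t_next + eps:
            snapshots.append((state.time, state.lag_profile(stage="sample")))
            next_sample += sample_every

    return SimulationResult(
        state=state, somites=tuple(somites), snapshots=tuple(snapshots)
    )


_COMPARE_GRID = np.linspace(0.0, 1.0, 201)


def run_to_steady_state(
    clock: ClockParams | PeriodGradient,
    regime: RegimeParams,
    n: int | None = None,
    tolerance: float = 1e-9,
    max_cycles: int = 500,
    initial_profile="synchronized",
    seed: int | None = None,
) -> SteadyStateResult:
    """Iterate formation cycles until the post-formation lag profile stops
    changing (sup norm on a fixed comparison grid), then package the emergent
    observables.

    For the constant-length regime the steady state is reached exactly once
    every initial cell has been flushed (about 1/β cycles); the no-growth
    regime converges geometrically while the PSM shrinks, so ``tolerance``
    should stay above the discretization floor there.
    """
    if not tolerance > 0:
        raise ParameterError(f"tolerance must be > 0, got {tolerance}")
    n0 = n if n is not None else regime.n
    if n0 is None:
        raise ParameterError("initial cell count n is required")
    grad = linear_gradient(clock) if isinstance(clock, ClockParams) else clock

    prev_psi = None
    prev_result: SimulationResult | None = None
    state = init_state(n0, grad, initial_profile, seed=seed)
    # run cycle by cycle, re-entering `run` with the current state
    somites_seen = 0
    result = None
    residual = math.inf
    for cycle in range(1, max_cycles + 1):
        result = _run_one_cycle(state, regime, somites_seen)
        state = result.state
        somites_seen += 1
        prof = state.lag_profile()
        psi = np.interp(_COMPARE_GRID, prof.x, prof.psi)
        if prev_psi is not None:
            residual = float(np.abs(psi - prev_psi).max())
            if residual < tolerance:
                return _package_steady_state(
                    prev_result, result, regime, cycle, residual
                )
        prev_psi = psi
        prev_result = result
    raise ConvergenceError(
        f"no steady state after {max_cycles} cycles; last residual {residual:.3e}",
        residual=residual,
    )


def _run_one_cycle(
    state: PSMState, regime: RegimeParams, formation_index: int
) -> SimulationResult:
    """Advance an existing state through exactly one formation."""
    timed = regime.rule == "timed"
    snapshots: list[tuple[float, PhaseProfile]] = []
    t0 = state.time
    if timed:
        n_growth = int(round(regime.ts / regime.tg))
        for j in range(1, n_growth + 1):
            state = step(state, t0 + j * regime.tg - state.time)
            state = add_posterior_cell(state)
        if abs(state.time - (t0 + regime.ts)) > 1e-9:
            state = step(state, t0 + regime.ts - state.time)
        r = n_growth
    else:
        rate = _threshold_rate(state)
        if rate <= 0:
            raise StagnationError("flat gradient: the threshold rule never fires")
        gap = regime.phi_before - state.delta_phi
        if gap > 0:
            state = step(state, gap / rate)
        r = None
    snapshots.append((state.time, state.lag_profile(stage="pre")))
    state, record = form_somite(state, regime, index=formation_index, removal_count=r)
    snapshots.append((state.time, state.lag_profile(stage="post")))
    return SimulationResult(state=state, somites=(record,), snapshots=tuple(snapshots))


def _package_steady_state(
    prev_result: SimulationResult,
    result: SimulationResult,
    regime: RegimeParams,
    cycles: int,
    residual: float,
) -> SteadyStateResult:
    record = result.somites[-1]
    pre = next(p for t, p in result.snapshots if p.stage == "pre")
    post = next(p for t, p in result.snapshots if p.stage == "post")
    prev_record = prev_result.somites[-1]
    ts = record.time - prev_record.time
    phi_before = pre.span
    return SteadyStateResult(
        post=post,
        pre=pre,
        phi_before=phi_before,
        phi_width=record.phase_span,
        beta=record.beta,
        ts=ts,
        shrink_factor=record.len_after / prev_record.len_after,
        regime="constant-length" if regime.grows else "no-growth",
        iterations=cycles,
        residual=residual,
        meta={"n_post": record.len_after, "cells_removed": record.cells_removed},
    )
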