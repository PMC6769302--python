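"""Shape, wave, scaling and sensitivity diagnostics of phase profiles.

The central prediction separating the two growth regimes is the curvature of
the steady-state phase profile: concave when the PSM length is constant,
slightly convex (near linear) when growth has stopped.  Curvature controls
the kinematics of the phase waves (concave ⇒ waves decelerate towards the
anterior) and how strongly an error in the measured somite phase width
propagates into its physical width (a steep anterior profile damps errors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from . import constraints, continuum
from .errors import ParameterError
from .gradients import ClockParams, PeriodGradient, linear_gradient
from .profiles import PhaseProfile, SteadyStateResult

TWO_PI = 2.0 * math.pi

__all__ = [
    "ConcavitySummary",
    "OracleIncrement",
    "HeatmapGrid",
    "WaveTrack",
    "SensitivityResult",
    "concavity_index",
    "concavity_oracle_increment",
    "fractional_width_from_phase_width",
    "perturbation_width_curve",
    "phi_before_heatmap",
    "track_wave",
    "width_error_sensitivity",
    "scaling_deviation",
]


# ---------------------------------------------------------------------------
# profile shape


@dataclass(frozen=True)
class ConcavitySummary:
    classification: str  # concave | convex | linear | mixed
    n_positive: int
    n_negative: int
    max_second_difference: float
    min_second_difference: float
    mean_second_difference: float
    second_differences: np.ndarray


def concavity_index(profile: PhaseProfile, tol: float = 1e-8) -> ConcavitySummary:
    """Classify the curvature of φ(x) from central second differences.

    Works on non-uniform grids: curvature estimates are normalized to the
    mean grid spacing, so on a uniform grid they equal the plain second
    differences ``np.diff(phi, 2)``.  A profile is concave when no second
    difference exceeds ``tol``, convex when none is below ``−tol``.
    """
    x, phi = profile.x, profile.phi
    if x.size < 5:
        raise ParameterError(f"need at least 5 grid points, got {x.size}")
    h_ref = float(np.mean(np.diff(x)))
    fwd = (phi[2:] - phi[1:-1]) / (x[2:] - x[1:-1])
    bwd = (phi[1:-1] - phi[:-2]) / (x[1:-1] - x[:-2])
    curv = 2.0 * (fwd - bwd) / (x[2:] - x[:-2])  # second-derivative estimate
    d2 = curv * h_ref**2
    n_pos = int(np.sum(d2 > tol))
    n_neg = int(np.sum(d2 < -tol))
    if n_pos == 0 and n_neg == 0:
        cls = "linear"
    elif n_pos == 0:
        cls = "concave"
    elif n_neg == 0:
        cls = "convex"
    else:
        cls = "mixed"
    return ConcavitySummary(
        classification=cls,
        n_positive=n_pos,
        n_negative=n_neg,
        max_second_difference=float(d2.max()),
        min_second_difference=float(d2.min()),
        mean_second_difference=float(d2.mean()),
        second_differences=d2,
    )


@dataclass(frozen=True)
class OracleIncrement:
    """Growth of the phase difference between two nearby material points
    over one formation cycle, computed two independent ways."""

    delta_phi_direct: float  # difference of the two exact trajectory gains
    delta_phi_expansion: float  # first-order quadrature along one trajectory
    delta_phi_initial: float  # δφ_ε from the steady profile at t = 0
    ratio: float  # 1 + Δφ_ε/δφ_ε; > 1 for any increasing gradient


def concavity_oracle_increment(
    x_star: float,
    eps: float,
    clock: ClockParams | PeriodGradient,
    beta: float,
    ts: float | None = None,
    quad_points: int = 32768,
) -> OracleIncrement:
    """Numerical oracle for the concavity argument (constant-length regime).

    Two cells start a cycle at x* and x* + ε.  Their phase difference grows
    by Δφ_ε = G(x*) − G(x* + ε) (exact trajectory gains) and, to first order
    in ε, by ε ∫ 2π T′(x(t)) / T(x(t))² · (L0/L(t)) dt along the x*
    trajectory.  Both are returned together with the steepening ratio
    1 + Δφ_ε/δφ_ε of the phase-profile gradient, which exceeds 1 whenever
    the gradient increases (and equals 1 exactly for a flat gradient).
    """
    if not 0.0 <= x_star < 1.0:
        raise ParameterError(f"x_star must be in [0, 1), got {x_star}")
    if not 0.0 < eps < 1.0 - x_star:
        raise ParameterError(f"eps must be in (0, 1 - x_star), got {eps}")
    if isinstance(clock, ClockParams) and ts is None:
        ts = clock.t0
    if ts is None:
        raise ParameterError("ts is required when a bare gradient is supplied")
    grad = linear_gradient(clock) if isinstance(clock, ClockParams) else clock

    a_pair = np.array([1.0 - x_star, 1.0 - x_star - eps])
    g1, g2 = continuum.phase_gain(grad, a_pair, np.zeros(2), ts, beta)
    direct = float(g1 - g2)

    # first-order expansion along the x* trajectory (midpoint rule on a fine
    # grid keeps tabulated-gradient slope discontinuities harmless)
    t = (np.arange(quad_points) + 0.5) * (ts / quad_points)
    L = 1.0 + beta * t / ts
    x_t = 1.0 - (1.0 - x_star) / L
    integrand = TWO_PI * grad.derivative(x_t) / grad(x_t) ** 2 / L
    expansion = float(eps * integrand.sum() * (ts / quad_points))

    if grad.is_flat:
        return OracleIncrement(direct, expansion, 0.0, 1.0)
    delta0 = float(
        continuum.psi_post(grad, beta, ts, x_star + eps)
        - continuum.psi_post(grad, beta, ts, x_star)
    )
    return OracleIncrement(direct, expansion, delta0, 1.0 + direct / delta0)


# ---------------------------------------------------------------------------
# phase width <-> fractional width


def fractional_width_from_phase_width(
    result: SteadyStateResult, phi_width: float
) -> float:
    """Convert a somite phase width (radians) to a fractional width β.

    Locates the cut point on the pre-formation profile where the anterior
    phase span equals ``phi_width`` and expresses the cut-off physical width
    relative to the post-formation PSM length.  Applying it to the regime's
    own emergent phase width returns the regime's own β.
    """
    if not 0 < phi_width < result.phi_before:
        raise ParameterError(
            f"phi_width must lie in (0, Phi_before = {result.phi_before:g}), "
            f"got {phi_width}"
        )
    pre = result.pre
    psi = PchipInterpolator(pre.x, pre.psi)
    target = pre.psi[-1] - phi_width
    x_cut = brentq(lambda z: psi(z) - target, 0.0, 1.0, xtol=1e-13)
    if result.regime == "constant-length":
        # pre length 1 + β, post length 1
        return (1.0 - x_cut) * (1.0 + result.beta)
    # no growth: pre length equals the length at formation; post length is
    # shrink_factor times that
    return (1.0 - x_cut) / result.shrink_factor


def perturbation_width_curve(
    clock: ClockParams,
    k: int,
    xis,
    result: SteadyStateResult,
) -> pd.DataFrame:
    """Phase width and fractional width of somites vs. uniform period
    perturbation ξ, mapped through the given (unperturbed) steady profile.

    The phase-width column is the closed-form perturbed constraint (shared
    with :mod:`psmclock.constraints`); the β column converts each phase
    width through the pre-formation profile of ``result``.  Both columns are
    non-increasing in ξ.
    """
    rows = []
    for xi in xis:
        frac = constraints.phase_width_perturbed(clock.lam, k, xi)
        rows.append(
            {
                "xi": float(xi),
                "phi_width_frac": frac,
                "beta": fractional_width_from_phase_width(result, frac * TWO_PI),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# constraint surface


@dataclass(frozen=True)
class HeatmapGrid:
    """Emergent Φ_before (radians) over a (λ, β) grid; ``log_phi_before``
    is the natural-log transform used for display."""

    lam_values: np.ndarray
    beta_values: np.ndarray
    phi_before: np.ndarray  # shape (len(lam_values), len(beta_values))

    @property
    def log_phi_before(self) -> np.ndarray:
        return np.log(self.phi_before)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lambda": lam,
                "beta": b,
                "phi_before_rad": self.phi_before[i, j],
            }
            for i, lam in enumerate(self.lam_values)
            for j, b in enumerate(self.beta_values)
        ]
        return pd.DataFrame(rows)


def phi_before_heatmap(
    lam_values, beta_values, t0: float = 130.0, ts: float | None = None
) -> HeatmapGrid:
    """Emergent total phase difference before formation over a (λ, β) grid.

    Each cell runs the constant-length continuum solution with Ts = T0 (one
    formation per posterior oscillation) and records the emergent Φ_before.
    Φ_before decreases with β at fixed λ, increases with λ at fixed β, and
    is ≈ 2π along the line β ≈ λ/2.
    """
    lam_values = np.asarray(lam_values, dtype=float)
    beta_values = np.asarray(beta_values, dtype=float)
    if np.any(lam_values <= 0) or np.any(beta_values <= 0):
        raise ParameterError("heatmap grids must be positive")
    if ts is None:
        ts = t0
    out = np.empty((lam_values.size, beta_values.size))
    for i, lam in enumerate(lam_values):
        grad = linear_gradient(ClockParams(t0=t0, lam=lam))
        for j, b in enumerate(beta_values):
            out[i, j] = continuum.emergent_phi_before(grad, b, ts)
    return HeatmapGrid(lam_values=lam_values, beta_values=beta_values, phi_before=out)


# ---------------------------------------------------------------------------
# wave kinematics


@dataclass(frozen=True)
class WaveTrack:
    """Trajectory of one iso-phase point crossing the PSM."""

    level: float  # tracked phase level, radians (mod 2π)
    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray  # dx/dt by central differences, len(times) - 1 midpoints

    def mean_velocity(self, x_lo: float = 0.0, x_hi: float = 1.0) -> float:
        mid_x = 0.5 * (self.positions[1:] + self.positions[:-1])
        mask = (mid_x >= x_lo) & (mid_x <= x_hi)
        if not mask.any():
            raise ParameterError(f"no velocity samples in [{x_lo}, {x_hi}]")
        return float(self.velocities[mask].mean())


def track_wave(snapshots, level: float = 0.0) -> WaveTrack:
    """Track a kinematic wave through a sequence of profile snapshots.

    ``snapshots`` is an iterable of ``(time, PhaseProfile)`` with strictly
    increasing times (e.g. from the discrete simulator's ``sample_every``
    output).  The tracked point is the location where the unwrapped phase
    equals a fixed constant congruent to ``level`` mod 2π, chosen so the
    wave starts as far posterior as possible at the first snapshot; the
    point then drifts anteriorward and the track ends when it exits at
    x = 1.
    """
    snaps = [(float(t), p) for t, p in snapshots]
    if len(snaps) < 3:
        raise ParameterError("need at least 3 snapshots to track a wave")
    t0, p0 = snaps[0]
    post0, ant0 = p0.phi[0], p0.phi[-1]
    # largest c <= phi(0) with c ≡ level (mod 2π); must lie within the span
    c = level + TWO_PI * math.floor((post0 - level) / TWO_PI)
    if c < ant0:
        raise ParameterError(
            "no iso-phase crossing of the requested level in the first snapshot"
        )
    times, positions = [], []
    for t, p in snaps:
        if c > p.phi[0] or c < p.phi[-1]:
            break
        # phi decreases with x: interpolate on the reversed axis
        xq = float(np.interp(c, p.phi[::-1], p.x[::-1]))
        times.append(t)
        positions.append(xq)
    if len(times) < 3:
        raise ParameterError("wave exits the PSM too quickly to sample velocities")
    times = np.asarray(times)
    positions = np.asarray(positions)
    vel = np.diff(positions) / np.diff(times)
    return WaveTrack(level=level, times=times, positions=positions, velocities=vel)


# ---------------------------------------------------------------------------
# error sensitivity and scaling


@dataclass(frozen=True)
class SensitivityResult:
    delta_phi: float
    base_beta: float
    width_error: float  # β(φ~ + δφ) − β(φ~), finite difference
    first_order: float  # δφ / (local ψ slope at the cut), length-converted


def width_error_sensitivity(
    result: SteadyStateResult, delta_phi: float
) -> SensitivityResult:
    """Effect of a phase-width measurement error δφ on the somite width.

    Finite-difference via :func:`fractional_width_from_phase_width`, plus
    the first-order estimate δφ/|dψ/dx| at the cut point (converted to the
    same post-formation length units).  The steeper the anterior profile,
    the smaller both numbers.
    """
    base = fractional_width_from_phase_width(result, result.phi_width)
    if delta_phi == 0.0:
        return SensitivityResult(0.0, base, 0.0, 0.0)
    shifted = fractional_width_from_phase_width(result, result.phi_width + delta_phi)
    pre = result.pre
    psi = PchipInterpolator(pre.x, pre.psi)
    target = pre.psi[-1] - result.phi_width
    x_cut = brentq(lambda z: psi(z) - target, 0.0, 1.0, xtol=1e-13)
    slope = float(psi.derivative()(x_cut))
    if result.regime == "constant-length":
        scale = 1.0 + result.beta
    else:
        scale = 1.0 / result.shrink_factor
    return SensitivityResult(
        delta_phi=delta_phi,
        base_beta=base,
        width_error=shifted - base,
        first_order=delta_phi / slope * scale,
    )


def scaling_deviation(
    profiles, continuum_profile: PhaseProfile
) -> pd.DataFrame:
    """Sup-norm distance of discrete lag profiles to the continuum profile.

    Profiles are interpolated onto the continuum grid; distances are
    reported in radians and as fractions of 2π (the package reporting
    unit).  Distance should fall as the cell count N grows — the scaling
    property of the pattern.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ParameterError("need at least two discrete profiles")
    ref_x = continuum_profile.x
    ref_psi = continuum_profile.psi
    rows = []
    for p in profiles:
        psi = np.interp(ref_x, p.x, p.psi)
        d = float(np.abs(psi - ref_psi).max())
        rows.append(
            {
                "n": p.n_cells,
                "sup_distance_rad": d,
                "sup_distance_frac": d / TWO_PI,
            }
        )
    return pd.DataFrame(rows).sort_values("n", ignore_index=True)
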