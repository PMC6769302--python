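"""Closed-form constraints of the somitogenesis steady state.

In a steady state of the phase pattern, the total posterior-to-anterior phase
difference across the PSM, Δφ(t) = φ(x=0) − φ(x=1), grows linearly between
somite formations,

    Δφ(t) = Φ_before − φ~ + 2π λ / (T0 (1 + λ)) · t,

and the growth over one formation period must equal the phase width φ~ of the
somite that is cut off.  With the formation period locked to a multiple
k of the posterior period T0, this forces

    φ~ = 2π k λ / (1 + λ),

a constraint tying the gradient slope λ to the somite phase width, with the
mouse values λ ≈ 0.266 ⇔ φ~ ≈ 0.21·2π, k = 1.  A uniform additive period
perturbation ξT0 generalizes this to φ~(ξ) = 2π k λ / (1 + λ + ξ).

Phase widths are passed to and returned from the ``*_frac`` style operations
as fractions of 2π (the reporting convention used throughout the package);
``delta_phi_trajectory`` and ``formation_period_from_phase_width`` work in
radians, the internal storage unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateGradientError, ParameterError

__all__ = [
    "RegimeParams",
    "phase_width_from_lambda",
    "lambda_from_phase_width",
    "phase_width_perturbed",
    "delta_phi_trajectory",
    "formation_period_from_phase_width",
    "constraint_summary",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class RegimeParams:
    """Growth-and-removal regime of the PSM.

    Attributes
    ----------
    tg : float or None
        Interval between posterior cell additions, minutes. ``None`` switches
        growth off (the end-of-somitogenesis regime).
    rule : str
        Formation rule: ``"timed"`` (a somite forms every ``ts`` minutes and
        removes the ``ts/tg`` cells added since the last one) or
        ``"threshold"`` (a somite forms when the phase difference across the
        PSM reaches ``phi_before`` and removes the anterior-most cells
        spanning ``phi_width`` of phase).
    ts : float or None
        Formation period in minutes (timed rule).
    phi_before : float or None
        Threshold total phase difference, radians (threshold rule).
    phi_width : float or None
        Somite phase width, radians (threshold rule).
    k : int
        Number of full phase waves spanning the PSM (``phi_before = 2πk`` in
        the canonical threshold setting). Default 1, as observed in mouse.
    n : int or None
        Post-formation cell count of the discrete PSM.
    beta : float or None
        Fractional somite width (somite width over post-formation PSM
        length); in steady state ``beta = ts / (n * tg)``.
    """

    tg: float | None = None
    rule: str = "timed"
    ts: float | None = None
    phi_before: float | None = None
    phi_width: float | None = None
    k: int = 1
    n: int | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.rule not in ("timed", "threshold"):
            raise ParameterError(f"rule must be 'timed' or 'threshold', got {self.rule!r}")
        if self.tg is not None and not self.tg > 0:
            raise ParameterError(f"tg must be > 0 or None, got {self.tg}")
        if self.k < 1:
            raise ParameterError(f"k must be a positive integer, got {self.k}")
        if self.n is not None and self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        if self.beta is not None and not self.beta > 0:
            raise ParameterError(f"beta must be > 0, got {self.beta}")
        if self.rule == "timed":
            if self.ts is None or not self.ts > 0:
                raise ParameterError("timed rule requires ts > 0")
            if self.tg is None:
                raise ParameterError(
                    "timed rule requires tg (removal count is ts/tg); "
                    "use the threshold rule for a non-growing PSM"
                )
        else:
            if self.phi_before is None or self.phi_width is None:
                raise ParameterError("threshold rule requires phi_before and phi_width")
            if not 0 < self.phi_width < self.phi_before:
                raise ParameterError(
                    f"need 0 < phi_width < phi_before, got "
                    f"phi_width={self.phi_width}, phi_before={self.phi_before}"
                )
        # consistency: beta = ts / (n tg) whenever all three are specified
        if None not in (self.beta, self.ts, self.n, self.tg):
            implied = self.ts / (self.n * self.tg)
            if not math.isclose(self.beta, implied, rel_tol=1e-9):
                raise ParameterError(
                    f"inconsistent regime: beta={self.beta} but ts/(n*tg)={implied}"
                )

    @property
    def grows(self) -> bool:
        return self.tg is not None


def phase_width_from_lambda(lam: float, k: int = 1) -> float:
    """Somite phase width (fraction of 2π) implied by gradient slope ``lam``.

    φ~ / 2π = k λ / (1 + λ); strictly increasing in both λ and k.
    """
    if lam < 0:
        raise ParameterError(f"lam must be >= 0, got {lam}")
    if k < 1:
        raise ParameterError(f"k must be a positive integer, got {k}")
    return k * lam / (1.0 + lam)


def lambda_from_phase_width(phi_frac: float, k: int = 1) -> float:
    """Gradient slope implied by a somite phase width (fraction of 2π).

    Inverse of :func:`phase_width_from_lambda`; requires ``phi_frac < k``.
    """
    if k < 1:
        raise ParameterError(f"k must be a positive integer, got {k}")
    if phi_frac < 0:
        raise ParameterError(f"phi_frac must be >= 0, got {phi_frac}")
    if phi_frac >= k:
        raise ParameterError(
            f"phase width fraction {phi_frac} >= k = {k}: no finite slope exists"
        )
    r = phi_frac / k
    return r / (1.0 - r)


def phase_width_perturbed(lam: float, k: int = 1, xi: float = 0.0) -> float:
    """Phase width (fraction of 2π) under a uniform period perturbation ξT0.

    φ~(ξ) / 2π = k λ / (1 + λ + ξ); decreasing in ξ, equal to
    :func:`phase_width_from_lambda` at ξ = 0.
    """
    if lam < 0:
        raise ParameterError(f"lam must be >= 0, got {lam}")
    if k < 1:
        raise ParameterError(f"k must be a positive integer, got {k}")
    if not 1.0 + lam + xi > 0:
        raise ParameterError(f"need 1 + lam + xi > 0, got lam={lam}, xi={xi}")
    return k * lam / (1.0 + lam + xi)


def delta_phi_trajectory(
    phi_before: float, phi_width: float, lam: float, t0: float, t
):
    """Total phase difference Δφ(t) across the PSM, radians, t minutes after a
    somite formed.

    Affine in t: intercept Φ_before − φ~, slope 2πλ / (T0 (1 + λ)).
    Accepts scalar or array ``t``.
    """
    if not t0 > 0:
        raise ParameterError(f"t0 must be > 0, got {t0}")
    if lam < 0:
        raise ParameterError(f"lam must be >= 0, got {lam}")
    slope = TWO_PI * lam / (t0 * (1.0 + lam))
    return phi_before - phi_width + slope * t


def formation_period_from_phase_width(phi_width: float, lam: float, t0: float) -> float:
    """Formation period Ts (minutes) implied by a phase width (radians).

    Inverts φ~ = 2π (Ts/T0) λ/(1+λ).  A flat gradient admits no finite Ts
    (the phase difference never grows) and raises
    :class:`~psmclock.errors.DegenerateGradientError`.
    """
    if not phi_width > 0:
        raise ParameterError(f"phi_width must be > 0, got {phi_width}")
    if not t0 > 0:
        raise ParameterError(f"t0 must be > 0, got {t0}")
    if lam == 0:
        raise DegenerateGradientError(
            "lam = 0: the phase difference across the PSM never grows, "
            "so no finite formation period exists"
        )
    if lam < 0:
        raise ParameterError(f"lam must be >= 0, got {lam}")
    return phi_width * t0 * (1.0 + lam) / (TWO_PI * lam)


def constraint_summary(
    lam: float | None = None,
    phi_frac: float | None = None,
    k: int = 1,
    xi: float = 0.0,
    t0: float = 130.0,
) -> dict:
    """All mutually determined constraint quantities from one given one.

    Exactly one of ``lam`` / ``phi_frac`` must be supplied; the other is
    inferred, along with the perturbed phase width, the formation period and
    the Δφ growth slope.  Returned values use the package reporting
    conventions (phase widths as fractions of 2π, times in minutes).
    """
    if (lam is None) == (phi_frac is None):
        raise ParameterError("supply exactly one of lam / phi_frac")
    if lam is None:
        lam = lambda_from_phase_width(phi_frac, k)
    base_frac = phase_width_from_lambda(lam, k)
    pert_frac = phase_width_perturbed(lam, k, xi)
    ts = formation_period_from_phase_width(base_frac * TWO_PI, lam, t0) if lam > 0 else None
    return {
        "lam": lam,
        "k": k,
        "xi": xi,
        "t0_min": t0,
        "phi_width_frac": base_frac,
        "phi_width_rad": base_frac * TWO_PI,
        "phi_width_frac_perturbed": pert_frac,
        "ts_min": ts,
        "delta_phi_slope_rad_per_min": TWO_PI * lam / (t0 * (1.0 + lam)),
    }
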