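"""Phase-profile containers shared by the discrete and continuum solvers."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ParameterError

TWO_PI = 2.0 * math.pi

__all__ = ["PhaseProfile", "SteadyStateResult"]


@dataclass(frozen=True)
class PhaseProfile:
    """A scaled phase profile on x ∈ [0, 1].

    ``phi`` holds unwrapped phase values (radians) posterior→anterior; the lag
    form ``psi(x) = phi(0) − phi(x)`` is mod-2π free and is what steady states
    are compared on.  ``stage`` tags whether the profile was taken just after
    ("post") or just before ("pre") a somite formation; ``n_cells`` records
    the discrete cell count where applicable (None for continuum profiles).
    """

    x: np.ndarray
    phi: np.ndarray
    stage: str = "post"
    n_cells: int | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if x.ndim != 1 or x.shape != phi.shape:
            raise ParameterError("x and phi must be 1-d arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ParameterError("profile grid must be strictly increasing")
        if not (np.isclose(x[0], 0.0) and np.isclose(x[-1], 1.0)):
            raise ParameterError("profile grid must include x = 0 and x = 1")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "phi", phi)

    @property
    def psi(self) -> np.ndarray:
        """Lag values ψ(x) = φ(0) − φ(x); ψ(0) = 0."""
        return self.phi[0] - self.phi

    def psi_at(self, xq):
        """Monotone-cubic interpolation of ψ at arbitrary points in [0, 1]."""
        return PchipInterpolator(self.x, self.psi)(xq)

    @property
    def span(self) -> float:
        """Total phase difference across the profile, φ(0) − φ(1), radians."""
        return float(self.phi[0] - self.phi[-1])


@dataclass(frozen=True)
class SteadyStateResult:
    """Converged steady state of a growth/removal regime.

    Holds post- and pre-formation profiles plus the emergent observables:
    the total phase difference just before formation (``phi_before``, rad),
    the somite phase width (``phi_width``, rad), the fractional somite width
    ``beta``, the formation period ``ts`` (minutes) and, for the shrinking
    no-growth regime, the per-formation length ratio ``shrink_factor``
    (1.0 when the PSM length is constant).
    """

    post: PhaseProfile
    pre: PhaseProfile
    phi_before: float
    phi_width: float
    beta: float
    ts: float
    shrink_factor: float
    regime: str  # "constant-length" | "no-growth"
    iterations: int = 0
    residual: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def phi_width_frac(self) -> float:
        return self.phi_width / TWO_PI

    @property
    def phi_before_frac(self) -> float:
        return self.phi_before / TWO_PI

    def summary(self) -> dict:
        return {
            "regime": self.regime,
            "phi_before_rad": self.phi_before,
            "phi_before_frac": self.phi_before_frac,
            "phi_width_rad": self.phi_width,
            "phi_width_frac": self.phi_width_frac,
            "beta": self.beta,
            "ts_min": self.ts,
            "shrink_factor": self.shrink_factor,
            "iterations": self.iterations,
            "residual": self.residual,
        }
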