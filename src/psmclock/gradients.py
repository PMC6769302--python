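"""Period gradients across the presomitic mesoderm.

The segmentation clock slows from posterior to anterior: a cell at scaled
position ``x`` (0 = posterior tip, 1 = anterior front) oscillates with period
``T(x)``.  The canonical form, measured in mouse ex vivo cultures, is linear,

    T(x) = T0 * (1 + xi + lam * x),

with base period ``T0`` (minutes), slope ``lam`` (dimensionless) and an
optional uniform additive perturbation ``xi`` (in units of ``T0``) that models
e.g. a global change of Wnt/FGF signalling.  Arbitrary monotone gradients are
supported through tabulated samples joined by monotone piecewise-linear
interpolation, which is all the theory requires (any increasing ``T(x)``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import MonotonicityError, ParameterError

__all__ = [
    "ClockParams",
    "PeriodGradient",
    "linear_gradient",
    "tabulated_gradient",
    "gradient_from_csv",
]


@dataclass(frozen=True)
class ClockParams:
    """Parameters of the linear clock-period gradient.

    Attributes
    ----------
    t0 : float
        Base (posterior) oscillation period in minutes; must be positive.
    lam : float
        Slope of the period gradient; dimensionless, non-negative.
    xi : float
        Uniform additive period perturbation in units of ``t0``;
        ``1 + xi`` must stay positive so all periods remain positive.
    """

    t0: float = 130.0
    lam: float = 0.266
    xi: float = 0.0

    def __post_init__(self) -> None:
        if not self.t0 > 0:
            raise ParameterError(f"t0 must be > 0, got {self.t0}")
        if self.lam < 0:
            raise ParameterError(f"lam must be >= 0, got {self.lam}")
        if not 1.0 + self.xi > 0:
            raise ParameterError(f"1 + xi must be > 0, got xi = {self.xi}")


@dataclass(frozen=True)
class PeriodGradient:
    """A validated period gradient ``T(x)`` on the scaled PSM axis.

    Internally stored as a piecewise-affine function: on the segment
    ``[knots[j], knots[j+1]]`` the period is ``a[j] + b[j] * x``.  A linear
    gradient is a single segment.  The piecewise-affine form is what the
    continuum solvers exploit: phase-gain integrals along material
    trajectories are then available in closed form.
    """

    kind: str  # "linear" | "tabulated"
    knots: tuple[float, ...]
    a: tuple[float, ...]  # intercepts, one per segment
    b: tuple[float, ...]  # slopes, one per segment

    def __call__(self, x):
        """Evaluate ``T(x)`` for scalar or array ``x`` in [0, 1]."""
        xv = np.asarray(x, dtype=float)
        seg = np.clip(np.searchsorted(self.knots, xv, side="right") - 1, 0, len(self.a) - 1)
        av = np.asarray(self.a)[seg]
        bv = np.asarray(self.b)[seg]
        out = av + bv * xv
        return out if out.ndim else float(out)

    def derivative(self, x):
        """Slope ``dT/dx``; piecewise constant (left-continuous at knots)."""
        xv = np.asarray(x, dtype=float)
        seg = np.clip(np.searchsorted(self.knots, xv, side="right") - 1, 0, len(self.a) - 1)
        out = np.asarray(self.b)[seg] + 0.0 * xv
        return out if out.ndim else float(out)

    @property
    def is_flat(self) -> bool:
        return all(bj == 0.0 for bj in self.b)

    def segments(self) -> Iterable[tuple[float, float, float, float]]:
        """Yield ``(x_lo, x_hi, a, b)`` for each affine segment."""
        for j in range(len(self.a)):
            yield self.knots[j], self.knots[j + 1], self.a[j], self.b[j]


def linear_gradient(params: ClockParams) -> PeriodGradient:
    """Build the linear gradient ``T(x) = t0 * (1 + xi + lam * x)``.

    Satisfies ``T(0) = t0 (1 + xi)`` and ``T(1) = t0 (1 + xi + lam)``.
    """
    a0 = params.t0 * (1.0 + params.xi)
    b0 = params.t0 * params.lam
    return PeriodGradient(kind="linear", knots=(0.0, 1.0), a=(a0,), b=(b0,))


def tabulated_gradient(samples: Sequence[tuple[float, float]]) -> PeriodGradient:
    """Build a monotone piecewise-linear gradient from ``(x, period)`` samples.

    The samples must be sorted in ``x``, lie within [0, 1], have positive
    periods and be non-decreasing; a decreasing pair raises
    :class:`~psmclock.errors.MonotonicityError` naming the offending pair.
    The table must cover both endpoints ``x = 0`` and ``x = 1``.
    """
    if len(samples) == 0:
        raise ParameterError("empty gradient table")
    xs = np.asarray([s[0] for s in samples], dtype=float)
    ts = np.asarray([s[1] for s in samples], dtype=float)
    if len(samples) < 2:
        raise ParameterError("gradient table needs at least two samples")
    if np.any(np.diff(xs) <= 0):
        raise ParameterError("gradient table x values must be strictly increasing")
    if xs[0] < 0 or xs[-1] > 1:
        raise ParameterError("gradient table x values must lie within [0, 1]")
    if not (np.isclose(xs[0], 0.0) and np.isclose(xs[-1], 1.0)):
        raise ParameterError("gradient table must cover x = 0 and x = 1")
    if np.any(ts <= 0):
        raise ParameterError("gradient periods must be positive")
    drops = np.nonzero(np.diff(ts) < 0)[0]
    if drops.size:
        j = int(drops[0])
        raise MonotonicityError(xs[j], ts[j], xs[j + 1], ts[j + 1])
    b = np.diff(ts) / np.diff(xs)
    a = ts[:-1] - b * xs[:-1]
    return PeriodGradient(
        kind="tabulated", knots=tuple(xs), a=tuple(a), b=tuple(b)
    )


def gradient_from_csv(path: str | Path) -> PeriodGradient:
    """Read a tabulated gradient from a two-column CSV ``x,period_min``."""
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["x", "period_min"]:
            raise ParameterError(
                f"expected CSV header 'x,period_min', got {reader.fieldnames!r}"
            )
        for row in reader:
            rows.append((float(row["x"]), float(row["period_min"])))
    return tabulated_gradient(rows)
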