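"""Scenario configuration: schema, built-in scenarios, YAML round-trip.

A :class:`ScenarioConfig` fully determines a run: the clock gradient, the
growth/removal regime and the solver settings.  Phase quantities in config
files are written as fractions of 2π (``phi_before_frac: 1.0`` means one
full wave), matching the package reporting convention; they are converted
to radians when the runtime parameter objects are built.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .constraints import RegimeParams
from .gradients import ClockParams, PeriodGradient, linear_gradient, tabulated_gradient

TWO_PI = 2.0 * math.pi

__all__ = ["ScenarioConfig", "ClockModel", "RegimeModel", "SolverModel", "builtin_scenarios", "read_config", "write_config"]


class ClockModel(BaseModel):
    t0: float = Field(..., gt=0, description="base (posterior) period, minutes")
    lam: float = Field(0.266, ge=0, description="period-gradient slope")
    xi: float = Field(0.0, description="uniform additive perturbation, units of t0")

    @model_validator(mode="after")
    def _check_positive_periods(self):
        if not 1.0 + self.xi > 0:
            raise ValueError(f"1 + xi must be > 0, got xi = {self.xi}")
        return self


class RegimeModel(BaseModel):
    rule: Literal["timed", "threshold"] = "timed"
    tg: Optional[float] = Field(None, gt=0, description="growth interval, minutes; null = no growth")
    ts: Optional[float] = Field(None, gt=0, description="formation period, minutes (timed rule)")
    phi_before_frac: Optional[float] = Field(
        None, gt=0, description="threshold phase difference, fraction of 2π"
    )
    phi_width_frac: Optional[float] = Field(
        None, gt=0, description="somite phase width, fraction of 2π"
    )
    k: int = Field(1, ge=1, description="number of waves spanning the PSM")
    n: Optional[int] = Field(None, ge=2, description="post-formation cell count (discrete)")
    beta: Optional[float] = Field(None, gt=0, description="fractional somite width (continuum)")


class SolverModel(BaseModel):
    grid_size: int = Field(201, ge=50)
    tolerance: float = Field(1e-9, gt=0)
    max_cycles: int = Field(500, ge=1)
    dt_max: Optional[float] = Field(None, gt=0)
    seed: int = 0


class ScenarioConfig(BaseModel):
    """A fully specified, runnable scenario."""

    name: str
    method: Literal["discrete", "continuum"] = "discrete"
    clock: ClockModel
    regime: RegimeModel = RegimeModel()
    solver: SolverModel = SolverModel()
    gradient_table: Optional[list[tuple[float, float]]] = Field(
        None, description="optional (x, period) samples overriding the linear gradient"
    )
    outdir: Optional[str] = None

    def clock_params(self) -> ClockParams:
        return ClockParams(t0=self.clock.t0, lam=self.clock.lam, xi=self.clock.xi)

    def gradient(self) -> PeriodGradient:
        if self.gradient_table is not None:
            return tabulated_gradient(self.gradient_table)
        return linear_gradient(self.clock_params())

    def regime_params(self) -> RegimeParams:
        r = self.regime
        return RegimeParams(
            tg=r.tg,
            rule=r.rule,
            ts=r.ts,
            phi_before=None if r.phi_before_frac is None else r.phi_before_frac * TWO_PI,
            phi_width=None if r.phi_width_frac is None else r.phi_width_frac * TWO_PI,
            k=r.k,
            n=r.n,
            beta=r.beta,
        )


def builtin_scenarios() -> list[ScenarioConfig]:
    """The named study scenarios, runnable offline.

    ``mouse-constant-length-N`` reproduce the constant-length mouse regime
    (T0 = 130 min, λ = 0.266, one formation per posterior period, sawtooth
    growth of N/7 cells per cycle) at several cell counts plus the continuum
    limit; ``mouse-no-growth`` is the end-of-somitogenesis regime (threshold
    at one full wave, somites of 0.21·2π phase); ``flat-gradient`` and
    ``quadratic-gradient`` are degenerate/nonlinear fixtures.
    """
    scenarios: list[ScenarioConfig] = []
    for n in (7, 14, 70):
        r = n // 7
        scenarios.append(
            ScenarioConfig(
                name=f"mouse-constant-length-{n}",
                method="discrete",
                clock=ClockModel(t0=130.0, lam=0.266, xi=0.0),
                regime=RegimeModel(
                    rule="timed", ts=130.0, tg=130.0 / r, n=n, beta=1.0 / 7.0
                ),
            )
        )
    scenarios.append(
        ScenarioConfig(
            name="mouse-constant-length-continuum",
            method="continuum",
            clock=ClockModel(t0=130.0, lam=0.266, xi=0.0),
            regime=RegimeModel(rule="timed", ts=130.0, beta=1.0 / 7.0),
        )
    )
    scenarios.append(
        ScenarioConfig(
            name="mouse-no-growth",
            method="continuum",
            clock=ClockModel(t0=130.0, lam=0.266, xi=0.0),
            regime=RegimeModel(
                rule="threshold",
                phi_before_frac=1.0,
                phi_width_frac=0.21,
                n=2000,
            ),
            solver=SolverModel(grid_size=1001, tolerance=1e-10),
        )
    )
    scenarios.append(
        ScenarioConfig(
            name="flat-gradient",
            method="discrete",
            clock=ClockModel(t0=130.0, lam=0.0, xi=0.0),
            regime=RegimeModel(rule="timed", ts=130.0, tg=26.0, n=10, beta=0.5),
        )
    )
    xs = [i / 100.0 for i in range(101)]
    table = [(x, 130.0 * (1.0 + 0.266 * x * x)) for x in xs]
    scenarios.append(
        ScenarioConfig(
            name="quadratic-gradient",
            method="continuum",
            clock=ClockModel(t0=130.0, lam=0.266, xi=0.0),
            regime=RegimeModel(rule="timed", ts=130.0, beta=1.0 / 7.0),
            gradient_table=table,
        )
    )
    return scenarios


def read_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario file (schema errors name fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioConfig.model_validate(data)


def write_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as YAML; round-trips losslessly through read_config."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
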