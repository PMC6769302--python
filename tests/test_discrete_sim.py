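import math

import numpy as np
import pytest

from psmclock import (
    ClockParams,
    RegimeParams,
    add_posterior_cell,
    form_somite,
    init_state,
    linear_gradient,
    run,
    run_to_steady_state,
    step,
)
from psmclock.errors import ExhaustionError, ParameterError, StagnationError

TWO_PI = 2.0 * math.pi


class TestInitState:
    def test_synchronized(self, mouse_clock):
        s = init_state(10, mouse_clock)
        assert s.n == 10 and np.all(s.phases == 0.0)
        assert s.x[0] == 0.0 and s.x[-1] == 1.0

    def test_linear(self, mouse_clock):
        s = init_state(5, mouse_clock, initial_profile=("linear", TWO_PI))
        assert s.phases[0] == pytest.approx(TWO_PI)
        assert s.phases[-1] == 0.0
        assert np.allclose(np.diff(s.phases), -TWO_PI / 4)

    def test_random_reproducible(self, mouse_clock):
        a = init_state(20, mouse_clock, initial_profile="random", seed=42)
        b = init_state(20, mouse_clock, initial_profile="random", seed=42)
        c = init_state(20, mouse_clock, initial_profile="random", seed=43)
        assert np.array_equal(a.phases, b.phases)
        assert not np.array_equal(a.phases, c.phases)

    def test_explicit_array(self, mouse_clock):
        s = init_state(3, mouse_clock, initial_profile=[3.0, 2.0, 1.0])
        assert np.allclose(s.phases, [3.0, 2.0, 1.0])

    def test_wrong_length_rejected(self, mouse_clock):
        with pytest.raises(ParameterError):
            init_state(3, mouse_clock, initial_profile=[1.0, 2.0])

    def test_too_few_cells(self, mouse_clock):
        with pytest.raises(ParameterError):
            init_state(1, mouse_clock)


class TestStep:
    def test_exact_phase_update(self, mouse_clock, mouse_gradient):
        s = init_state(5, mouse_clock)
        dt = 17.3
        s2 = step(s, dt)
        assert s2.time == pytest.approx(dt)
        assert np.allclose(s2.phases, TWO_PI * dt / mouse_gradient(s.x))

    def test_composition_is_exact(self, mouse_clock):
        # two half steps equal one full step to rounding (no ODE error)
        s = init_state(8, mouse_clock)
        one = step(s, 50.0)
        two = step(step(s, 25.0), 25.0)
        assert np.allclose(one.phases, two.phases, rtol=0, atol=1e-12)

    def test_posterior_fastest(self, mouse_clock):
        s = step(init_state(5, mouse_clock), 10.0)
        assert np.all(np.diff(s.phases) < 0)

    def test_nonpositive_dt_rejected(self, mouse_clock):
        with pytest.raises(ParameterError):
            step(init_state(5, mouse_clock), 0.0)


class TestGrowthAndFormation:
    def test_growth_copies_posterior_phase(self, mouse_clock):
        s = step(init_state(5, mouse_clock), 10.0)
        s2 = add_posterior_cell(s)
        assert s2.n == 6
        assert s2.phases[0] == s.phases[0] == s2.phases[1]
        assert s2.events[-1][1] == "growth"

    def test_timed_removal_count(self, mouse_clock):
        regime = RegimeParams(rule="timed", ts=130.0, tg=13.0)
        s = step(init_state(20, mouse_clock), 130.0)
        s2, rec = form_somite(s, regime, removal_count=10)
        assert s2.n == 10 and rec.cells_removed == 10
        assert rec.beta == pytest.approx(1.0)
        assert rec.len_before == 20 and rec.len_after == 10

    def test_threshold_removes_smallest_sufficient_suffix(self, mouse_clock):
        regime = RegimeParams(rule="threshold", phi_before=TWO_PI, phi_width=1.0)
        s = init_state(11, mouse_clock, initial_profile=np.linspace(5.0, 0.0, 11))
        s2, rec = form_somite(s, regime)
        # phases step by 0.5; the smallest suffix spanning >= 1.0 is 2 cells
        assert rec.cells_removed == 2
        assert rec.phase_span == pytest.approx(1.0)

    def test_exhaustion(self, mouse_clock):
        regime = RegimeParams(rule="timed", ts=130.0, tg=13.0)
        s = init_state(5, mouse_clock)
        with pytest.raises(ExhaustionError):
            form_somite(s, regime, removal_count=4)


class TestRun:
    def test_formation_count_and_sawtooth(self, mouse_clock):
        regime = RegimeParams(rule="timed", ts=130.0, tg=65.0, n=14)
        res = run(mouse_clock, regime, n_formations=3)
        assert len(res.somites) == 3
        assert all(r.cells_removed == 2 for r in res.somites)
        assert res.state.n == 14  # back to post-formation size

    def test_requires_stopping_condition(self, mouse_clock):
        regime = RegimeParams(rule="timed", ts=130.0, tg=65.0, n=14)
        with pytest.raises(ParameterError):
            run(mouse_clock, regime)

    def test_flat_gradient_threshold_stagnates(self):
        flat = ClockParams(t0=130.0, lam=0.0)
        regime = RegimeParams(rule="threshold", phi_before=TWO_PI, phi_width=1.0)
        with pytest.raises(StagnationError):
            run(flat, regime, n=10, n_formations=1)

    def test_non_integer_ratio_warns_and_balances(self, mouse_clock):
        regime = RegimeParams(rule="timed", ts=130.0, tg=52.0, n=20)  # ratio 2.5
        with pytest.warns(UserWarning, match="not an integer"):
            res = run(mouse_clock, regime, n_formations=4)
        counts = [r.cells_removed for r in res.somites]
        assert sorted(set(counts)) == [2, 3]
        assert sum(counts) == 10  # 4 * 2.5: no drift

    def test_snapshots_bracket_formation(self, mouse_clock):
        regime = RegimeParams(rule="timed", ts=130.0, tg=65.0, n=14)
        res = run(mouse_clock, regime, n_formations=1)
        stages = [p.stage for _, p in res.snapshots]
        assert stages == ["pre", "post"]

    def test_threshold_fires_at_phi_before(self, mouse_clock):
        regime = RegimeParams(
            rule="threshold", phi_before=TWO_PI, phi_width=0.21 * TWO_PI
        )
        profile = np.linspace(0.9 * TWO_PI, 0.0, 200)
        res = run(mouse_clock, regime, n=200, initial_profile=profile, n_formations=1)
        pre = next(p for _, p in res.snapshots if p.stage == "pre")
        assert pre.span == pytest.approx(TWO_PI, rel=1e-9)


class TestRunToSteadyState:
    def test_mouse_70_emergent_width(self, discrete_steady_70):
        # emergent removed span = lambda/(1+lambda) of 2pi, not an input
        assert discrete_steady_70.phi_width_frac == pytest.approx(
            0.266 / 1.266, rel=1e-6
        )
        assert discrete_steady_70.ts == pytest.approx(130.0)
        assert discrete_steady_70.beta == pytest.approx(1.0 / 7.0)
        assert discrete_steady_70.shrink_factor == pytest.approx(1.0)
        assert discrete_steady_70.regime == "constant-length"

    def test_deterministic(self, mouse_clock, mouse_regime_70, discrete_steady_70):
        again = run_to_steady_state(mouse_clock, mouse_regime_70)
        assert np.array_equal(again.post.phi, discrete_steady_70.post.phi)
        assert again.ts == discrete_steady_70.ts

    def test_steady_state_is_fixed_point(self, mouse_clock, mouse_regime_70, discrete_steady_70):
        # restarting from the converged profile reproduces it after one cycle
        res = run(
            mouse_clock,
            mouse_regime_70,
            n=70,
            initial_profile=discrete_steady_70.post.phi,
            n_formations=1,
        )
        post = next(p for _, p in res.snapshots if p.stage == "post")
        assert np.allclose(post.psi, discrete_steady_70.post.psi, atol=1e-9)

    def test_independent_of_initial_profile(self, mouse_clock, mouse_regime_70, discrete_steady_70):
        res = run_to_steady_state(
            mouse_clock, mouse_regime_70, initial_profile="random", seed=7
        )
        assert np.allclose(res.post.psi, discrete_steady_70.post.psi, atol=1e-9)
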