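import math

import numpy as np
import pytest

from psmclock import ClockParams, PhaseProfile, linear_gradient
from psmclock.diagnostics import (
    concavity_index,
    concavity_oracle_increment,
    fractional_width_from_phase_width,
    perturbation_width_curve,
    phi_before_heatmap,
    scaling_deviation,
    track_wave,
    width_error_sensitivity,
)
from psmclock.errors import ParameterError

TWO_PI = 2.0 * math.pi


def _profile(x, phi):
    return PhaseProfile(x=np.asarray(x), phi=np.asarray(phi))


class TestConcavityIndex:
    def test_synthetic_shapes(self):
        x = np.linspace(0, 1, 101)
        assert concavity_index(_profile(x, -((x - 1) ** 2))).classification == "concave"
        assert concavity_index(_profile(x, x**2)).classification == "convex"
        assert concavity_index(_profile(x, 3 * x + 1)).classification == "linear"
        assert concavity_index(_profile(x, np.sin(6 * x))).classification == "mixed"

    def test_nonuniform_grid(self):
        x = np.sort(np.concatenate([[0.0, 1.0], np.random.default_rng(0).uniform(0, 1, 60)]))
        assert concavity_index(_profile(x, x**2)).classification == "convex"

    def test_needs_five_points(self):
        x = np.linspace(0, 1, 4)
        with pytest.raises(ParameterError):
            concavity_index(_profile(x, x))

    def test_counts_and_extrema(self):
        x = np.linspace(0, 1, 51)
        s = concavity_index(_profile(x, x**2))
        assert s.n_negative == 0 and s.n_positive == 49
        assert s.min_second_difference > 0


class TestConcavityOracle:
    def test_expansion_matches_direct_to_second_order(self, mouse_clock):
        errs = {}
        for eps in (1e-2, 1e-3):
            o = concavity_oracle_increment(0.4, eps, mouse_clock, beta=1.0 / 7.0)
            errs[eps] = abs(o.delta_phi_direct - o.delta_phi_expansion)
        # O(eps^2): tenfold smaller eps shrinks the error ~hundredfold
        assert errs[1e-2] / errs[1e-3] > 30
        assert errs[1e-3] < 1e-5

    def test_ratio_exceeds_one_everywhere(self, mouse_clock, quadratic_gradient):
        for grad, ts in ((mouse_clock, None), (quadratic_gradient, 130.0)):
            for x_star in (0.0, 0.3, 0.7):
                for eps in (1e-2, 1e-3):
                    o = concavity_oracle_increment(
                        x_star, eps, grad, beta=1.0 / 7.0, ts=ts
                    )
                    assert o.ratio > 1.0
                    assert o.delta_phi_direct > 0

    def test_flat_gradient_ratio_exactly_one(self):
        o = concavity_oracle_increment(
            0.3, 1e-3, ClockParams(t0=130.0, lam=0.0), beta=1.0 / 7.0
        )
        assert o.ratio == 1.0
        assert o.delta_phi_direct == pytest.approx(0.0, abs=1e-15)

    def test_domain_validation(self, mouse_clock):
        with pytest.raises(ParameterError):
            concavity_oracle_increment(1.0, 0.1, mouse_clock, beta=0.1)
        with pytest.raises(ParameterError):
            concavity_oracle_increment(0.9, 0.5, mouse_clock, beta=0.1)


class TestFractionalWidth:
    def test_self_consistency_constant_length(self, const_length_result):
        b = fractional_width_from_phase_width(
            const_length_result, const_length_result.phi_width
        )
        assert b == pytest.approx(const_length_result.beta, rel=1e-9)

    def test_self_consistency_no_growth(self, no_growth_result):
        b = fractional_width_from_phase_width(
            no_growth_result, no_growth_result.phi_width
        )
        assert b == pytest.approx(no_growth_result.beta, rel=1e-6)

    def test_monotone_in_phase_width(self, const_length_result):
        widths = np.linspace(0.1, 0.3, 7) * TWO_PI
        betas = [
            fractional_width_from_phase_width(const_length_result, w) for w in widths
        ]
        assert np.all(np.diff(betas) > 0)

    def test_out_of_range_rejected(self, const_length_result):
        with pytest.raises(ParameterError):
            fractional_width_from_phase_width(
                const_length_result, 2 * const_length_result.phi_before
            )


class TestPerturbationCurve:
    def test_non_increasing_in_xi(self, mouse_clock, const_length_result):
        df = perturbation_width_curve(
            mouse_clock, 1, np.linspace(-0.2, 0.5, 15), const_length_result
        )
        assert np.all(np.diff(df["phi_width_frac"]) < 0)
        assert np.all(np.diff(df["beta"]) < 0)

    def test_xi_zero_recovers_regime(self, mouse_clock, const_length_result):
        df = perturbation_width_curve(mouse_clock, 1, [0.0], const_length_result)
        assert df["beta"].iloc[0] == pytest.approx(const_length_result.beta, rel=1e-9)


class TestHeatmap:
    def test_monotonicity_small_grid(self):
        grid = phi_before_heatmap(np.linspace(0.1, 0.5, 5), np.linspace(0.05, 0.3, 5))
        # (i) increasing in lambda at fixed beta; (ii) decreasing in beta
        assert np.all(np.diff(grid.phi_before, axis=0) > 0)
        assert np.all(np.diff(grid.phi_before, axis=1) < 0)

    def test_frame_layout(self):
        grid = phi_before_heatmap([0.2, 0.3], [0.1, 0.2])
        df = grid.to_frame()
        assert list(df.columns) == ["lambda", "beta", "phi_before_rad"]
        assert len(df) == 4

    def test_positive_grids_required(self):
        with pytest.raises(ParameterError):
            phi_before_heatmap([0.0, 0.1], [0.1])


@pytest.fixture(scope="module")
def snapshots(mouse_clock, mouse_regime_70, discrete_steady_70):
    from psmclock import run

    sim = run(
        mouse_clock,
        mouse_regime_70,
        n=70,
        initial_profile=discrete_steady_70.post.phi,
        horizon=4 * 130.0,
        sample_every=2.0,
        snapshot_formations=False,
    )
    return [(t, p) for t, p in sim.snapshots if p.stage == "sample"]


class TestWaves:
    def test_wave_moves_anteriorward(self, snapshots):
        track = track_wave(snapshots)
        assert np.all(track.velocities > 0)
        assert track.positions[-1] > track.positions[0]

    def test_wave_decelerates(self, snapshots):
        # concave profile => the kinematic wave slows towards the anterior
        track = track_wave(snapshots)
        v_post = track.mean_velocity(0.0, 0.4)
        v_ant = track.mean_velocity(0.6, 1.0)
        assert v_ant < v_post

    def test_needs_enough_snapshots(self, snapshots):
        with pytest.raises(ParameterError):
            track_wave(snapshots[:2])


class TestSensitivity:
    def test_first_order_agrees(self, const_length_result):
        s = width_error_sensitivity(const_length_result, 0.01)
        assert s.width_error == pytest.approx(s.first_order, rel=0.05)

    def test_steeper_profile_damps_errors(self, const_length_result, no_growth_result):
        # constant-length profiles are steep at the anterior; no-growth ones
        # are shallow, so the same phase error costs more width there
        d_cl = width_error_sensitivity(const_length_result, 0.01).width_error
        d_ng = width_error_sensitivity(no_growth_result, 0.01).width_error
        assert 0 < d_cl < d_ng

    def test_zero_error(self, const_length_result):
        s = width_error_sensitivity(const_length_result, 0.0)
        assert s.width_error == 0.0 and s.first_order == 0.0


class TestScalingDeviation:
    def test_distance_decreases_with_n(
        self, mouse_clock, const_length_result
    ):
        from psmclock import RegimeParams, run_to_steady_state

        profiles = []
        for n in (7, 14, 70):
            r = n // 7
            regime = RegimeParams(rule="timed", ts=130.0, tg=130.0 / r, n=n)
            profiles.append(run_to_steady_state(mouse_clock, regime, n=n).post)
        df = scaling_deviation(profiles, const_length_result.post)
        d = df["sup_distance_rad"].to_numpy()
        assert np.all(np.diff(d) < 0)
        assert df["sup_distance_frac"].iloc[-1] == pytest.approx(
            d[-1] / TWO_PI, rel=1e-12
        )

    def test_needs_two_profiles(self, const_length_result):
        with pytest.raises(ParameterError):
            scaling_deviation([const_length_result.post], const_length_result.post)
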