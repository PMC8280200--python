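"""Activation functions, drift, and single-cell/population integration."""

import numpy as np
import pytest

import zfclock as z
from zfclock import _kernels
from zfclock.model import ClockState
from zfclock.trace import Trace
from zfclock.metrics import smooth


class TestActivation:
    def test_sequestration_free_repressor_limit(self):
        # with R = 0, (A-K)^2 + 4AK = (A+K)^2, so f = 1 exactly
        assert z.sequestration_activation(0.0, 1.0, 0.001) == pytest.approx(1.0, abs=1e-15)

    def test_sequestration_stoichiometric_point(self):
        # at R = A the closed form reduces to (-K + sqrt(K^2 + 4AK)) / (2A)
        K, A = 1e-6, 1.0
        expected = (-K + np.sqrt(K**2 + 4 * A * K)) / (2 * A)
        assert z.sequestration_activation(1.0, A, K) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.995e-4, rel=1e-3)

    def test_sequestration_approaches_piecewise(self):
        assert z.sequestration_activation(2.0, 1.0, 1e-12) == pytest.approx(
            z.piecewise_activation(2.0, 1.0), abs=1e-5
        )

    @pytest.mark.parametrize(
        "R,A,expected", [(0.5, 1.0, 0.5), (3.0, 1.0, 0.0), (2.0, 2.0, 0.0)]
    )
    def test_piecewise_branches(self, R, A, expected):
        assert z.piecewise_activation(R, A) == pytest.approx(expected)

    def test_nonpositive_activator_rejected(self):
        with pytest.raises(ValueError):
            z.piecewise_activation(1.0, 0.0)
        with pytest.raises(ValueError):
            z.sequestration_activation(1.0, -1.0, 0.1)

    def test_piecewise_limit_on_grid_and_decreasing_in_K(self):
        A = 1.0
        R = np.linspace(0, 2 * A, 501)
        diffs = [
            np.max(np.abs(z.sequestration_activation(R, A, K) - z.piecewise_activation(R, A)))
            for K in (1e-3, 1e-4, 1e-5)
        ]
        assert diffs[1] < 1e-2
        assert diffs[0] > diffs[1] > diffs[2]

    def test_bounded_in_unit_interval_for_nonnegative_repressor(self):
        R = np.linspace(0, 10, 200)
        f = z.sequestration_activation(R, 2.0, 0.01)
        assert np.all((f > 0) & (f <= 1))


class TestDrift:
    def test_zero_state(self):
        p = z.ClockParameters.with_equal_degradation(1.0, 0.2, i=0.5)
        assert z.drift(ClockState(0, 0, 0), p, 1) == pytest.approx((1.5, 0.0, 0.0))

    def test_hand_computed_rates(self):
        p = z.ClockParameters.with_equal_degradation(1.0, 0.2, i=0.3)
        rates = z.drift(ClockState(1.0, 2.0, 0.5), p, 0)
        assert rates == pytest.approx((0.3, 0.6, 1.9))

    def test_dark_fixed_point_has_zero_rates(self):
        p = z.ClockParameters.with_equal_degradation(3.5, 0.4)
        # steady state of the piecewise branch: R* = 1/(d^3 + 1/A)
        d, A = 0.4, 3.5
        R = 1.0 / (d**3 + 1.0 / A)
        P = R * d
        M = R * d * d
        rates = z.drift(ClockState(M, P, R), p, 0)
        assert np.allclose(rates, 0.0, atol=1e-12)

    def test_invalid_light_level(self):
        p = z.ClockParameters.with_equal_degradation(1.0, 0.2)
        with pytest.raises(ValueError):
            z.drift(ClockState(0, 0, 0), p, 2)


class TestParameters:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            z.ClockParameters(A=-1, d_M=0.1, d_P=0.1, d_R=0.1)
        with pytest.raises(ValueError):
            z.ClockParameters(A=1, d_M=0.0, d_P=0.1, d_R=0.1)
        with pytest.raises(ValueError):
            z.ClockParameters(A=1, d_M=0.1, d_P=0.1, d_R=0.1, sigma=-0.1)

    def test_equal_degradation_constructor(self):
        p = z.ClockParameters.with_equal_degradation(2.0, 0.3, i=0.1, sigma=0.05)
        assert p.equal_degradation
        assert p.d_M == p.d_P == p.d_R == 0.3

    def test_dict_round_trip(self):
        p = z.ClockParameters(A=1.5, d_M=0.2, d_P=0.25, d_R=0.3, i=0.1, sigma=0.02, K=1e-4)
        assert z.ClockParameters.from_dict(p.to_dict()) == p


class TestDeterministic:
    def test_fixed_point_stays_fixed(self):
        p = z.ClockParameters.with_equal_degradation(3.5, 0.4)
        d, A = 0.4, 3.5
        R = 1.0 / (d**3 + 1.0 / A)
        x0 = ClockState(R * d * d, R * d, R)
        traj = z.simulate_deterministic(p, z.constant(0, 48), x0=x0)
        assert np.max(np.abs(traj.states - np.array(x0))) < 1e-6

    def test_limit_cycle_period_self_consistent(self, control_params):
        traj = z.simulate_deterministic(control_params, z.constant(0, 480))
        times, _ = z.detect_peaks(Trace(traj.times, traj.luminescence).window(240, np.inf))
        intervals = np.diff(times)
        assert np.all(np.abs(intervals - intervals.mean()) / intervals.mean() < 0.01)

    def test_dt_refinement_converges(self, control_params):
        a = z.simulate_deterministic(control_params, z.constant(0, 240), dt=0.02)
        b = z.simulate_deterministic(control_params, z.constant(0, 240), dt=0.01)
        assert np.max(np.abs(a.states - b.states)) < 1e-3

    def test_small_K_trajectory_close_to_piecewise_limit(self, control_params):
        full = z.simulate_deterministic(control_params.replace(K=1e-4), z.constant(0, 48))
        limit = z.simulate_deterministic(control_params, z.constant(0, 240))
        amp = np.ptp(limit.luminescence[limit.times > 120])
        m = limit.times <= 48
        assert np.max(np.abs(full.luminescence - limit.luminescence[m])) < 0.02 * amp


class TestStochastic:
    def test_zero_noise_reduces_to_deterministic(self, control_params, entrained_x0):
        em = z.simulate_single_cell(
            control_params.replace(sigma=0.0), z.constant(0, 48), x0=entrained_x0
        )
        rk = z.simulate_deterministic(control_params, z.constant(0, 48), x0=entrained_x0)
        assert np.max(np.abs(em.luminescence - rk.luminescence)) < 0.05

    def test_seed_determinism(self, control_params, entrained_x0):
        kw = dict(x0=entrained_x0, rng_seed=42)
        a = z.simulate_single_cell(control_params, z.constant(0, 48), **kw)
        b = z.simulate_single_cell(control_params, z.constant(0, 48), **kw)
        c = z.simulate_single_cell(control_params, z.constant(0, 48), x0=entrained_x0, rng_seed=43)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.states, c.states)

    def test_one_step_variance_matches_euler_maruyama(self):
        # 500 replicate single steps from one state: var = sigma^2 * dt per variable
        sigma, dt = 0.3, 0.01
        light = np.zeros(1)
        finals = np.empty((500, 3))
        for s in range(500):
            states, _, status = _kernels.integrate_cell(
                1.0, 1.0, 1.0, 1.0, 0.2, 0.2, 0.2, 0.0, sigma, 0.0, False, light, dt, 1, s, 0
            )
            assert status == -1
            finals[s] = states[1]
        v = np.var(finals, axis=0, ddof=1)
        assert np.all(np.abs(v - sigma**2 * dt) < 0.2 * sigma**2 * dt)

    def test_nonfinite_state_reports_step(self):
        # enormous noise overflows the sequestration discriminant quickly
        p = z.ClockParameters.with_equal_degradation(1.0, 2.0, sigma=1e200, K=1e-4)
        with pytest.raises(z.IntegrationError, match="step"):
            z.simulate_single_cell(p, z.constant(0, 10), dt=0.1, record_dt=0.1)


class TestPopulation:
    def test_single_cell_equivalence_at_n_one(self, control_params, entrained_x0):
        proto = z.constant(0, 48)
        pop = z.simulate_population(
            control_params, proto, n=1, x0=entrained_x0, rng_seed=7, record_cells=1
        )
        cell = z.simulate_single_cell(control_params, proto, x0=entrained_x0, rng_seed=7)
        assert np.allclose(pop.mean_luminescence, cell.luminescence)
        assert np.allclose(pop.cells[0], cell.luminescence)

    def test_invalid_cell_count(self, control_params):
        with pytest.raises(ValueError):
            z.simulate_population(control_params, z.constant(0, 24), n=0)

    def test_mean_equals_average_of_retained_cells(self, control_params, entrained_x0):
        pop = z.simulate_population(
            control_params, z.constant(0, 48), n=20, x0=entrained_x0, rng_seed=3,
            record_cells=20, dt=0.02,
        )
        assert np.allclose(pop.cells.mean(axis=0), pop.mean_luminescence)

    def test_split_population_averaging_identity(self, control_params, entrained_x0):
        proto = z.concat(z.ld_cycle(12, 12, 3), z.constant(0, 72))
        full = z.simulate_population(
            control_params, proto, n=400, x0=entrained_x0, dt=0.02, rng_seed=10,
            record_cells=400,
        )
        h1 = z.simulate_population(control_params, proto, n=200, x0=entrained_x0, dt=0.02, rng_seed=11)
        h2 = z.simulate_population(control_params, proto, n=200, x0=entrained_x0, dt=0.02, rng_seed=12)
        comb = 0.5 * (h1.mean_luminescence + h2.mean_luminescence)
        sd = full.cells.std(axis=0, ddof=1)
        se_diff = sd * np.sqrt(1 / 400 + 1 / 400)  # both estimates average 400 cells
        diff = comb - full.mean_luminescence
        # the difference should be on the Monte-Carlo scale, not above it
        assert np.sqrt(np.mean(diff**2)) < 1.5 * np.sqrt(np.mean(se_diff**2))
        assert np.max(np.abs(diff)) < 5 * np.max(se_diff)

    def test_population_damps_while_cells_sustain(self, control_params, entrained_x0):
        """Desynchronization: population DD amplitude decays, single cells do not."""
        proto = z.concat(z.ld_cycle(12, 12, 3), z.constant(0, 144))
        pop = z.simulate_population(
            control_params, proto, n=1500, x0=entrained_x0, dt=0.02, rng_seed=5,
            record_cells=12,
        )
        tr = smooth(Trace(pop.times, pop.mean_luminescence).window(72, np.inf), 2.0)
        _, heights = z.detect_peaks(tr, min_distance_h=15)
        assert len(heights) >= 4
        assert np.all(np.diff(heights) < 0)  # each successive peak lower
        for cell in pop.cells:
            ctr = smooth(Trace(pop.times, cell).window(72, np.inf), 4.0)
            _, h = z.detect_peaks(ctr, min_distance_h=15)
            if len(h) >= 2:
                assert h[-1] >= 0.5 * h[0]

    def test_noise_strictly_lowers_third_dark_peak(self, control_params, entrained_x0):
        proto = z.concat(z.ld_cycle(12, 12, 3), z.constant(0, 144))
        third = []
        for sig in (0.005, 0.01, 0.02):
            pop = z.simulate_population(
                control_params.replace(sigma=sig), proto, n=1200, x0=entrained_x0,
                dt=0.02, rng_seed=5,
            )
            tr = smooth(Trace(pop.times, pop.mean_luminescence).window(72, np.inf), 2.0)
            _, heights = z.detect_peaks(tr, min_distance_h=15)
            third.append(heights[2])
        assert third[0] > third[1] > third[2]


class TestBurnIn:
    def test_returns_finite_state(self, control_params):
        x0 = z.burn_in_initial_state(control_params)
        assert np.all(np.isfinite(x0))

    def test_limit_cycle_convergence(self, control_params):
        x10 = np.array(z.burn_in_initial_state(control_params, days=10))
        x20 = np.array(z.burn_in_initial_state(control_params, days=20))
        assert np.max(np.abs(x20 - x10) / np.abs(x10)) < 0.01

    def test_restart_continues_periodically(self, control_params, entrained_x0):
        traj = z.simulate_deterministic(control_params, z.ld_cycle(12, 12, 6), x0=entrained_x0)
        times, _ = z.detect_peaks(Trace(traj.times, traj.luminescence))
        assert abs(np.diff(times)[0] - 24.0) < 0.02 * 24.0
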