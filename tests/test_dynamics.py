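"""Unit and property tests for the 2D Epileptor network simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vepcal.dynamics import (
    IntegrationDivergedError, NetworkModel, NoBifurcationError,
    critical_excitability, drift, isolated_fixed_points, simulate_ode,
    simulate_sde,
)


def iso(eta, tau=10.0, **kw):
    return NetworkModel(connectome=np.zeros((1, 1)),
                        excitability=np.array([eta]), timescale=tau, **kw)


class TestDrift:
    def test_hand_computed_value(self):
        m = iso(-1.6)
        dx, dz = drift(np.array([-2.5]), np.array([3.5]), m)
        assert dx[0] == pytest.approx(3.725, abs=1e-12)
        assert dz[0] == pytest.approx(-0.71, abs=1e-12)

    def test_vanishes_at_fixed_point(self):
        rep = isolated_fixed_points(-3.025, I=3.1, tau=10.0)
        fp = rep.fixed_points[0]
        dx, dz = drift(np.array([fp.x]), np.array([fp.z]), iso(-3.025))
        assert abs(dx[0]) < 1e-9 and abs(dz[0]) < 1e-9

    def test_equal_states_cancel_coupling(self):
        C = np.array([[0.0, 0.7], [0.7, 0.0]])
        m = NetworkModel(connectome=C, excitability=np.array([-2.0, -3.0]),
                         coupling=5.0, timescale=10.0)
        x = np.array([-1.3, -1.3])
        z = np.array([2.0, 2.0])
        dxc, dzc = drift(x, z, m)
        m0 = NetworkModel(connectome=C, excitability=np.array([-2.0, -3.0]),
                          coupling=0.0, timescale=10.0)
        dx0, dz0 = drift(x, z, m0)
        np.testing.assert_allclose(dzc, dz0, atol=1e-14)
        np.testing.assert_allclose(dxc, dx0, atol=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            drift(np.zeros(2), np.zeros(2), iso(-2.0))


class TestSimulateOde:
    def test_single_euler_step(self):
        t = simulate_ode(iso(-1.6), 0.1)
        assert t.x[1, 0] == pytest.approx(-2.5 + 0.1 * 3.725, abs=1e-14)
        assert t.z[1, 0] == pytest.approx(3.5 + 0.1 * (-0.71), abs=1e-14)

    def test_sample_count_and_grid(self):
        t = simulate_ode(iso(-3.0), 25.0)
        assert t.times.shape[0] == 251
        assert np.allclose(np.diff(t.times), 0.1)

    def test_constant_at_stable_fixed_point(self):
        rep = isolated_fixed_points(-3.5, tau=10.0)
        fp = next(f for f in rep.fixed_points if f.stable)
        m = NetworkModel(connectome=np.zeros((1, 1)),
                         excitability=np.array([-3.5]), timescale=10.0,
                         x0z0=(fp.x, fp.z))
        t = simulate_ode(m, 50.0)
        assert np.max(np.abs(t.x - fp.x)) < 1e-9
        assert np.max(np.abs(t.z - fp.z)) < 1e-9

    def test_decoupled_network_equals_independent_nodes(self):
        etas = [-1.6, -2.2, -3.5]
        net = NetworkModel(connectome=np.ones((3, 3)) - np.eye(3),
                           excitability=np.array(etas), coupling=0.0,
                           timescale=10.0)
        tn = simulate_ode(net, 200.0)
        for k, eta in enumerate(etas):
            ts = simulate_ode(iso(eta), 200.0)
            assert np.array_equal(tn.x[:, k], ts.x[:, 0])
            assert np.array_equal(tn.z[:, k], ts.z[:, 0])

    def test_rejects_noisy_model(self):
        with pytest.raises(ValueError, match="noise_std"):
            simulate_ode(iso(-2.0, noise_std=0.1), 10.0)

    def test_blowup_reports_step(self):
        m = NetworkModel(connectome=np.zeros((1, 1)),
                         excitability=np.array([-2.0]), timescale=10.0,
                         dt=10.0)  # absurd step forces divergence
        with pytest.raises(IntegrationDivergedError) as err:
            simulate_ode(m, 1000.0)
        assert err.value.step >= 1

    def test_euler_error_scales_linearly_with_dt(self):
        """Halving dt roughly halves the error against a fine reference."""
        def run(dt):
            m = NetworkModel(connectome=np.zeros((1, 1)),
                             excitability=np.array([-2.2]), timescale=10.0,
                             dt=dt)
            return simulate_ode(m, 20.0)

        ref = run(1e-3)
        e1 = abs(run(0.1).x[-1, 0] - ref.x[-1, 0])
        e2 = abs(run(0.05).x[-1, 0] - ref.x[-1, 0])
        assert 1.5 <= e1 / e2 <= 2.5


class TestSimulateSde:
    def test_zero_noise_equals_ode_bitwise(self, small_network):
        a = simulate_ode(small_network, 50.0)
        b = simulate_sde(small_network, 50.0, seed=123)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.z, b.z)

    def test_seed_reproducibility(self):
        m = iso(-3.5, noise_std=0.1)
        a = simulate_sde(m, 100.0, seed=7)
        b = simulate_sde(m, 100.0, seed=7)
        assert np.array_equal(a.x, b.x)
        c = simulate_sde(m, 100.0, seed=8)
        assert not np.array_equal(a.x, c.x)

    def test_late_time_spread_matches_monte_carlo(self):
        """Stationary fluctuation size agrees with a brute-force re-run
        ensemble within a factor of 5."""
        m = iso(-3.5, noise_std=0.1)
        ref = simulate_sde(m, 2000.0, seed=0)
        s0 = np.std(ref.x[10000:, 0])
        others = [np.std(simulate_sde(m, 2000.0, seed=s).x[10000:, 0])
                  for s in range(1, 11)]
        mc = np.mean(others)
        assert mc / 5 < s0 < mc * 5


class TestStability:
    def test_known_stable_fixed_point(self):
        rep = isolated_fixed_points(-3.025, I=3.1, tau=10.0)
        assert len(rep.fixed_points) >= 1
        fp = rep.fixed_points[0]
        assert fp.x == pytest.approx(-2.0, abs=1e-9)
        assert fp.z == pytest.approx(4.1, abs=1e-9)
        assert fp.stable
        assert fp.trace == pytest.approx(-4.1, abs=1e-9)
        assert fp.det == pytest.approx(0.8, abs=1e-9)

    def test_ez_regime_is_unstable_and_oscillates(self):
        rep = isolated_fixed_points(-1.6, tau=10.0)
        assert not rep.has_stable
        t = simulate_ode(iso(-1.6), 500.0)
        late = t.x[2500:, 0]
        assert late.max() - late.min() > 1.0  # sustained oscillation

    def test_hz_regime_converges(self):
        t = simulate_ode(iso(-3.5), 500.0)
        assert np.var(t.x[4000:, 0]) < 1e-6

    @given(eta=st.floats(-4.0, -1.2), tau=st.floats(5.0, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_nullcline_residuals_below_tolerance(self, eta, tau):
        rep = isolated_fixed_points(eta, I=3.1, tau=tau)
        assert 1 <= len(rep.fixed_points) <= 3
        for fp in rep.fixed_points:
            r1 = 1 - fp.x ** 3 - 2 * fp.x ** 2 - fp.z + 3.1
            r2 = 4 * (fp.x - eta) - fp.z
            assert abs(r1) < 1e-9 and abs(r2) < 1e-9


class TestCriticalExcitability:
    def test_matches_printed_value_at_large_tau(self):
        grid = np.arange(-2.2, -1.89, 0.01)
        m = iso(-3.0, tau=100.0)
        ec = critical_excitability(m, grid)
        assert ec == pytest.approx(-2.05, rel=0.01)

    def test_below_threshold_has_stable_point(self):
        grid = np.arange(-2.2, -1.89, 0.01)
        ec = critical_excitability(iso(-3.0, tau=10.0), grid)
        for eta in (ec - 0.01, ec - 0.1, ec - 0.5):
            assert isolated_fixed_points(eta, tau=10.0).has_stable
        assert not isolated_fixed_points(ec + 0.01, tau=10.0).has_stable

    def test_agrees_with_brute_force_scan(self):
        tau = 20.0
        grid = np.arange(-2.2, -1.89, 0.005)
        ec = critical_excitability(iso(-3.0, tau=tau), grid)
        flags = [isolated_fixed_points(e, tau=tau).has_stable for e in grid]
        k = next(i for i, f in enumerate(flags) if not f)
        assert grid[k - 1] <= ec <= grid[k]

    def test_requires_bracketing_grid(self):
        with pytest.raises(NoBifurcationError):
            critical_excitability(iso(-3.0), np.array([-4.0, -3.9, -3.8]))

    def test_requires_uncoupled_model(self, small_network):
        with pytest.raises(ValueError, match="K = 0"):
            critical_excitability(small_network, np.arange(-2.2, -1.9, 0.01))


class TestModelValidation:
    def test_rejects_nonsquare_connectome(self):
        with pytest.raises(ValueError, match="square"):
            NetworkModel(connectome=np.zeros((2, 3)),
                         excitability=np.zeros(2))

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError, match="non-negative"):
            NetworkModel(connectome=np.array([[0.0, -1.0], [1.0, 0.0]]),
                         excitability=np.zeros(2))

    def test_rejects_bad_eta_length(self):
        with pytest.raises(ValueError, match="length"):
            NetworkModel(connectome=np.zeros((2, 2)),
                         excitability=np.zeros(3))
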