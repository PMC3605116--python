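"""Chemostat ODE integration and the simulation loop."""

import numpy as np
import pytest

from coevostat import (AdsorptionMatrix, ConsistencyError, InvalidParameterError,
                       ModelParameters, NumericalFailureError, SystemState,
                       cull_extinct, derivatives, make_single_peak, nbar, rbar,
                       rk4_step, simulate)

PHI = 0.104e-8


def _empty_state(R, params):
    return SystemState(t=0.0, R=R,
                       host_bins=np.zeros(0, dtype=np.int64),
                       host_density=np.zeros(0),
                       phage_bins=np.zeros(0, dtype=np.int64),
                       phage_density=np.zeros(0), rho=params.rho)


def _theta_for(state, params, scheme="gaussian"):
    return AdsorptionMatrix.build(state.host_bins, state.phage_bins,
                                  params.phi, params.s, scheme=scheme,
                                  rho=params.rho)


class TestDerivatives:
    def test_washout_equilibrium(self, params, single_peak):
        state = _empty_state(params.R0, params)
        dR, dN, dV = derivatives(state, params, _theta_for(state, params),
                                 single_peak)
        assert dR == 0.0 and dN.size == 0 and dV.size == 0

    def test_single_host_at_rbar_is_stationary(self, params, single_peak):
        # oracle: the analytic limiting resource concentration
        delta = single_peak.delta(0.5)
        state = SystemState.from_communities({0.5: 1e5}, {}, R=rbar(delta, params))
        _, dN, _ = derivatives(state, params, _theta_for(state, params), single_peak)
        assert dN[0] == pytest.approx(0.0, abs=1e-12)

    def test_phage_stationary_at_nhat(self, params, single_peak):
        # dV/dt = 0 exactly when N = omega / (beta theta)
        n_hat = params.omega / (params.beta * params.phi)
        state = SystemState.from_communities({0.5: n_hat}, {0.5: 1e6}, R=2.0)
        _, _, dV = derivatives(state, params, _theta_for(state, params), single_peak)
        assert dV[0] == pytest.approx(0.0, abs=1e-9)

    def test_against_pure_python_oracle(self, params, single_peak, toy_state):
        # brute-force per-strain loop, no numpy linear algebra
        theta = _theta_for(toy_state, params)
        dR, dN, dV = derivatives(toy_state, params, theta, single_peak)
        R = toy_state.R
        monod = params.gamma * R / (R + params.K)
        delta = [single_peak.table[b] for b in toy_state.host_bins]
        exp_dR = -params.omega * (R - params.R0)
        for i, n in enumerate(toy_state.host_density):
            exp_dR -= params.epsilon * monod * delta[i] * n
        assert dR == pytest.approx(exp_dR, rel=1e-12)
        for i, n in enumerate(toy_state.host_density):
            lysis = sum(theta.theta[i, j] * v
                        for j, v in enumerate(toy_state.phage_density))
            want = -params.omega * n + monod * delta[i] * n - lysis * n
            assert dN[i] == pytest.approx(want, rel=1e-12)
        for j, v in enumerate(toy_state.phage_density):
            prod = sum(params.beta * theta.theta[i, j] * n
                       for i, n in enumerate(toy_state.host_density))
            assert dV[j] == pytest.approx(-params.omega * v + prod * v, rel=1e-12)

    def test_resource_biomass_coupling(self, params, single_peak, toy_state):
        # the uptake drain on R equals epsilon times the gross growth sum
        theta = _theta_for(toy_state, params)
        dR, dN, dV = derivatives(toy_state, params, theta, single_peak)
        monod = params.gamma * toy_state.R / (toy_state.R + params.K)
        gross = sum(monod * single_peak.table[b] * n
                    for b, n in zip(toy_state.host_bins, toy_state.host_density))
        supply = -params.omega * (toy_state.R - params.R0)
        assert dR == pytest.approx(supply - params.epsilon * gross, rel=1e-12)

    def test_dimension_mismatch_raises(self, params, single_peak, toy_state):
        with pytest.raises(ConsistencyError):
            derivatives(toy_state, params, np.zeros((2, 2)), single_peak)


class TestRK4Step:
    def test_fixed_point_unchanged(self, params, single_peak):
        state = _empty_state(params.R0, params)
        new = rk4_step(state, params, _theta_for(state, params), single_peak)
        assert new.R == pytest.approx(params.R0)
        assert new.t == params.dt

    def test_resource_relaxation_closed_form(self, params, single_peak):
        # empty chemostat from R=0: R(t) = R0 (1 - exp(-omega t))
        state = _empty_state(0.0, params)
        theta = _theta_for(state, params)
        for _ in range(500):
            state = rk4_step(state, params, theta, single_peak)
        t = state.t
        want = params.R0 * (1.0 - np.exp(-params.omega * t))
        assert state.R == pytest.approx(want, rel=1e-10)

    def test_matches_fine_euler_oracle(self, params, single_peak):
        # one RK4 predator-prey step vs 1000 explicit-Euler micro-steps
        state = SystemState.from_communities({0.5: 5e4}, {0.5: 8e5}, R=2.2)
        theta = _theta_for(state, params)
        rk = rk4_step(state, params, theta, single_peak)
        R, N, V = state.R, state.host_density.copy(), state.phage_density.copy()
        h = params.dt / 1000.0
        for _ in range(1000):
            st = SystemState(t=0.0, R=R, host_bins=state.host_bins,
                             host_density=N, phage_bins=state.phage_bins,
                             phage_density=V, rho=params.rho)
            dR, dN, dV = derivatives(st, params, theta, single_peak)
            R, N, V = R + h * dR, N + h * dN, V + h * dV
        assert rk.R == pytest.approx(R, rel=1e-6)
        assert rk.host_density[0] == pytest.approx(N[0], rel=1e-6)
        assert rk.phage_density[0] == pytest.approx(V[0], rel=1e-6)

    def test_nonfinite_state_raises_named_error(self, params, single_peak):
        state = SystemState.from_communities({0.5: 1e300}, {}, R=1e300)
        theta = _theta_for(state, params)
        with pytest.raises(NumericalFailureError) as err:
            rk4_step(state, params, theta, single_peak, dt=1e280)
        assert err.value.variable in ("R", "N", "V")

    def test_nonpositive_dt_rejected(self, params, single_peak, toy_state):
        with pytest.raises(InvalidParameterError):
            rk4_step(toy_state, params, _theta_for(toy_state, params),
                     single_peak, dt=0.0)


class TestCull:
    def test_below_threshold_removed(self, params):
        state = SystemState.from_communities({0.2: 0.999}, {}, R=2.0)
        assert cull_extinct(state).host_bins.size == 0

    def test_boundary_retained(self, params):
        state = SystemState.from_communities({0.2: 1.0}, {}, R=2.0)
        assert cull_extinct(state).host_bins.size == 1

    def test_mixed_roster(self):
        state = SystemState.from_communities(
            {0.1: 2e3, 0.2: 0.5, 0.3: 1.7}, {0.1: 0.2, 0.5: 3e5}, R=2.0)
        culled = cull_extinct(state)
        assert sorted(culled.host_density) == [1.7, 2e3]
        assert list(culled.phage_density) == [3e5]


class TestSimulate:
    def test_phage_free_converges_to_analytic_equilibrium(self, params, single_peak):
        p = params.replace(M_B=0.0, M_V=0.0, V_init=0.0, h_init=0.5, T=3e5)
        traj = simulate(p, single_peak, seed=0, output_stride=10000)
        f = traj.final
        delta = single_peak.delta(0.5)
        assert f.R == pytest.approx(rbar(delta, params), rel=1e-3)
        assert f.host_density[0] == pytest.approx(nbar(delta, params), rel=1e-3)

    def test_same_seed_bit_identical(self, params, single_peak):
        p = params.replace(T=2e4)
        a = simulate(p, single_peak, seed=7, output_stride=100)
        b = simulate(p, single_peak, seed=7, output_stride=100)
        assert a.times.size == b.times.size
        for sa, sb in zip(a.samples, b.samples):
            assert sa.R == sb.R
            np.testing.assert_array_equal(sa.host_bins, sb.host_bins)
            np.testing.assert_array_equal(sa.host_density, sb.host_density)
            np.testing.assert_array_equal(sa.phage_density, sb.phage_density)

    def test_nonnegativity_preserved(self, params, single_peak):
        p = params.replace(T=5e4, M_B=1e-5, M_V=1e-5)
        traj = simulate(p, single_peak, seed=3, output_stride=500)
        for s in traj.samples:
            assert s.R >= 0
            assert (s.host_density >= 0).all()
            assert (s.phage_density >= 0).all()

    def test_timestep_halving_changes_little(self, params, single_peak):
        # phage-free benchmark: dt 10 -> 5 shifts the final state by < 0.1%
        base = params.replace(M_B=0.0, M_V=0.0, V_init=0.0, T=2e5)
        a = simulate(base, single_peak, seed=0, output_stride=10**9).final
        b = simulate(base.replace(dt=5.0), single_peak, seed=0,
                     output_stride=10**9).final
        assert a.R == pytest.approx(b.R, rel=1e-3)
        assert a.total_host_density == pytest.approx(b.total_host_density, rel=1e-3)

    def test_trajectory_roundtrip_csv(self, tmp_path, params, single_peak):
        p = params.replace(T=1e4)
        traj = simulate(p, single_peak, seed=1, output_stride=500)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        text = out.read_text()
        assert "# seed: 1" in text
        assert "time,variable,genotype_bin,value" in text

    def test_strict_scheme_runs(self, params, single_peak):
        p = params.replace(T=1e4, M_B=0.0, M_V=0.0)
        traj = simulate(p, single_peak, seed=0, scheme="strict",
                        output_stride=500)
        assert traj.final.R > 0
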