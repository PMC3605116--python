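"""Closed-form equilibrium theory."""

import numpy as np
import pytest
from scipy.optimize import brentq

from coevostat import (CannotEstablishError, InvalidParameterError,
                       ModelParameters, NoGrowthError, nbar, phage_limited,
                       rbar, rhat, steady_state_diversity)
from coevostat.steady_state import diversity_scan, equal_growth_collapse_check

POOL = tuple(np.round(np.linspace(1.2, 0.8, 11), 10))


class TestRbar:
    def test_fastest_strain_value(self, params):
        # direct substitution: omega K / (gamma delta_max - omega)
        want = 0.0033 * 4.0 / (0.0123 * 1.2 - 0.0033)
        assert rbar(1.2, params) == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(1.1518, abs=5e-5)

    def test_no_growth_below_washout(self, params):
        with pytest.raises(NoGrowthError):
            rbar(params.omega / params.gamma * (1 - 1e-9), params)
        with pytest.raises(NoGrowthError):
            rbar(0.1, params)

    def test_diverges_approaching_pole(self, params):
        near_pole = params.omega / params.gamma * (1 + 1e-9)
        assert rbar(near_pole, params) > 1e6

    def test_decreasing_in_delta(self, params):
        deltas = np.linspace(0.8, 1.2, 20)
        values = [rbar(d, params) for d in deltas]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestNbar:
    def test_printed_form_equivalence(self, params):
        # the nested printed expression, transcribed literally, at 20
        # random parameter points
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = ModelParameters(
                omega=rng.uniform(0.001, 0.01), K=rng.uniform(1, 8),
                gamma=rng.uniform(0.005, 0.05), R0=rng.uniform(5, 50),
                epsilon=rng.uniform(1e-7, 1e-5))
            delta = rng.uniform(0.8, 1.2)
            if p.gamma * delta <= p.omega:
                continue
            rb_expr = p.omega * p.K / (p.gamma * delta - p.omega)
            if rb_expr >= p.R0:
                continue
            printed = (-p.omega * (rb_expr - p.R0) * (rb_expr + p.K)
                       / (p.epsilon * p.gamma * delta * rb_expr))
            assert nbar(delta, p) == pytest.approx(printed, rel=1e-12)

    def test_carrying_capacity_value(self, params):
        # cross-checked against the simulate() convergence test
        assert nbar(1.2, params) == pytest.approx(403141.36, rel=1e-6)

    def test_washout_boundary_gives_zero(self, params):
        rb = rbar(1.2, params)
        p = params.replace(R0=rb)
        assert nbar(1.2, p) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(CannotEstablishError):
            nbar(1.2, params.replace(R0=rb * 0.99))

    def test_increasing_in_supply(self, params):
        values = [nbar(1.2, params.replace(R0=r0)) for r0 in (1.5, 2.2, 3.0)]
        assert values[0] < values[1] < values[2]


class TestPhageLimited:
    def test_nhat_hand_substitution(self, params):
        n_hat, _ = phage_limited(params, 1.2)
        assert n_hat == pytest.approx(0.0033 / (71 * 0.104e-8), rel=1e-12)
        assert n_hat == pytest.approx(4.469e4, rel=1e-3)

    def test_phage_limit_below_carrying_capacity(self, params):
        n_hat, _ = phage_limited(params, 1.2)
        assert n_hat < nbar(1.2, params)

    def test_vhat_increases_with_delta(self, params):
        R = 2.0
        vhats = [phage_limited(params, d, R=R)[1] for d in (0.9, 1.0, 1.2)]
        assert vhats[0] < vhats[1] < vhats[2]

    def test_vhat_consistent_with_host_stationarity(self, params):
        # at V = Vhat the host equation balances: growth = washout + lysis
        delta, R = 1.1, 1.9
        _, vhat = phage_limited(params, delta, R=R)
        growth = params.gamma * R * delta / (R + params.K)
        assert growth == pytest.approx(params.omega + params.phi * vhat, rel=1e-12)


class TestRhat:
    def test_supply_limit_without_consumption(self, params):
        p = params.replace(epsilon=1e-30)
        assert rhat(1, [1.2], p) == pytest.approx(params.R0, rel=1e-9)

    def test_strictly_decreasing_in_i(self, params):
        values = [rhat(i, POOL, params) for i in range(1, len(POOL) + 1)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_against_root_finding_oracle(self, params):
        # independent 1-D root of dR/dt = 0 with one strain pinned at Nhat
        n_hat = params.omega / (params.beta * params.phi)

        def dRdt(R):
            return (-params.omega * (R - params.R0)
                    - params.epsilon * params.gamma * R * n_hat * 1.2 / (R + params.K))

        root = brentq(dRdt, 1e-9, params.R0)
        assert rhat(1, [1.2], params) == pytest.approx(root, rel=1e-10)

    def test_out_of_range_i_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            rhat(0, [1.2], params)
        with pytest.raises(InvalidParameterError):
            rhat(2, [1.2], params)


class TestDiversityCascade:
    def test_benchmark_pool_supports_six_strains(self, params):
        assert steady_state_diversity(POOL, params) == 6

    def test_single_viable_strain(self, params):
        assert steady_state_diversity([1.2], params) == 1

    def test_monotone_in_supply_vs_bruteforce(self, params):
        # brute-force cascade written out longhand, per R0
        def brute(r0):
            p = dict(omega=0.0033, K=4.0, gamma=0.0123, epsilon=2.6e-6,
                     beta=71.0, phi=0.104e-8)
            for i in range(1, len(POOL) + 1):
                rb = p["omega"] * p["K"] / (p["gamma"] * POOL[i - 1] - p["omega"])
                C = p["epsilon"] * p["gamma"] * sum(POOL[:i]) / (p["beta"] * p["phi"])
                b = r0 - p["K"] - C
                rh = (b + np.sqrt(b * b + 4 * r0 * p["K"])) / 2
                if rb > rh:
                    return i
            return len(POOL)

        xs = []
        for r0 in (1.7, 2.2, 2.7):
            x = steady_state_diversity(POOL, params.replace(R0=r0))
            assert x == brute(r0)
            xs.append(x)
        assert xs[0] <= xs[1] <= xs[2]
        assert xs[0] < xs[2]

    def test_all_phage_limited_flag(self, params):
        pred = steady_state_diversity([1.2, 1.1], params.replace(R0=50.0),
                                      full=True)
        assert pred.diversity == 2
        assert pred.all_phage_limited

    def test_prediction_bundle_consistency(self, params):
        pred = steady_state_diversity(POOL, params, full=True)
        assert pred.r_star == pytest.approx(rbar(1.2, params))
        assert pred.n_star == pytest.approx(nbar(1.2, params))
        assert pred.n_hat == pytest.approx(params.omega / (params.beta * params.phi))
        assert len(pred.rhat_seq) == len(POOL)
        # the cascade inequality holds exactly at x and nowhere before
        for i in range(pred.diversity - 1):
            assert pred.rbar_seq[i] <= pred.rhat_seq[i]
        assert pred.rbar_seq[pred.diversity - 1] > pred.rhat_seq[pred.diversity - 1]

    def test_invalid_pools_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            steady_state_diversity([], params)
        with pytest.raises(InvalidParameterError):
            steady_state_diversity([1.0, 1.1], params)

    def test_scan_table(self, params):
        table = diversity_scan((1.7, 2.2, 2.7), POOL, params)
        assert list(table["x"]) == sorted(table["x"])
        assert table.loc[table["R0"] == 2.2, "x"].item() == 6


class TestEqualGrowthCorollary:
    def test_prediction_statement(self, params):
        pred = equal_growth_collapse_check(params, 1.1, 3)
        assert not pred.coexistence_stable
        assert pred.rbar == pytest.approx(rbar(1.1, params))

    def test_varied_growth_delegates_to_cascade(self, params):
        # with variation the cascade applies and predicts coexistence > 1
        assert steady_state_diversity(POOL, params) > 1
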