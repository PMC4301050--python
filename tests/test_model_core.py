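"""Closed-form equilibria, invasion criteria and stability analysis.

The closed forms are cross-checked against independent numerical oracles:
root-finding on the per-capita growth functions (brentq) and full
fixed-point solves of the rate field (scipy.optimize.fsolve), never against
the same algebra they implement.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq, fsolve

from protmut.model_core import (
    ClampedEnemyCollapseError,
    InfeasibleEquilibriumError,
    ModelParams,
    State,
    analytic_m_star,
    clamped_m_growth,
    derivatives,
    enemy_eq_density,
    enemy_invasion_rate,
    equilibria,
    host_enemy_eq_is_stable,
    host_eq_with_enemy,
    host_eq_with_mutualist,
    is_net_protective,
    jacobian,
    mutualist_eq_density,
    mutualist_invasion_rate,
    net_mutualism_U,
    random_params,
)


class TestModelParams:
    def test_rejects_nonpositive_u(self, worked_params):
        with pytest.raises(ValueError, match="u"):
            worked_params.replace(u=0.0)
        with pytest.raises(ValueError, match="u"):
            worked_params.replace(u=-1.0)

    def test_rejects_negative_q_but_allows_zero(self, worked_params):
        with pytest.raises(ValueError, match="q"):
            worked_params.replace(q=-0.1)
        assert worked_params.replace(q=0.0).q == 0.0

    def test_feasible_mutualist_is_printed_positivity_condition(self, worked_params):
        p = worked_params
        assert p.feasible_mutualist == (
            p.r * p.b * p.alpha * p.gamma > p.q * p.delta_M
        )
        # push q past the boundary q = r b alpha gamma / delta_M
        q_bound = p.r * p.b * p.alpha * p.gamma / p.delta_M
        assert not p.replace(q=2 * q_bound).feasible_mutualist

    def test_round_trips_through_dict(self, worked_params):
        assert ModelParams.from_dict(worked_params.to_dict()) == worked_params

    def test_from_dict_rejects_unknown_keys(self, worked_params):
        bad = {**worked_params.to_dict(), "bogus": 1.0}
        with pytest.raises(ValueError, match="bogus"):
            ModelParams.from_dict(bad)


class TestDerivatives:
    def test_no_host_both_symbionts_decline(self, worked_params):
        dH, dE, dM = derivatives(State(0.0, 5.0, 3.0), worked_params)
        assert dH == 0.0
        assert dE < 0
        assert dM < 0

    def test_host_enemy_equilibrium_is_fixed_point(self, worked_params):
        H = host_eq_with_enemy(worked_params)
        E = enemy_eq_density(worked_params)
        assert H == pytest.approx(1.0)
        assert E == pytest.approx(0.6)
        rates = derivatives(State(H, E, 0.0), worked_params)
        assert max(abs(x) for x in rates) < 1e-10

    def test_worked_example_rates(self, worked_params):
        # at (1, 0.6, 0) the mutualist per-capita rate alpha*gamma*b*H -
        # delta_M = 0.05 - 0.1, but M = 0 so dM/dt = 0 (absorbing boundary)
        rates = derivatives(State(1.0, 0.6, 0.0), worked_params)
        assert rates == pytest.approx((0.0, 0.0, 0.0))
        # with one mutualist present the per-capita rate is visible
        rates = derivatives(State(1.0, 0.6, 1.0), worked_params)
        assert rates[2] == pytest.approx(-0.05)

    def test_rejects_nonfinite_and_negative_states(self, worked_params):
        with pytest.raises(ValueError):
            derivatives(State(np.nan, 0.0, 0.0), worked_params)
        with pytest.raises(ValueError):
            derivatives(State(np.inf, 0.0, 0.0), worked_params)
        with pytest.raises(ValueError):
            derivatives(State(-1.0, 0.0, 0.0), worked_params)

    def test_boundary_absorption(self, worked_params, rng):
        """No species is spontaneously generated from density zero."""
        for _ in range(20):
            H, E, M = rng.uniform(0, 5, size=3)
            assert derivatives(State(0.0, E, M), worked_params)[0] == 0.0
            assert derivatives(State(H, 0.0, M), worked_params)[1] == 0.0
            assert derivatives(State(H, E, 0.0), worked_params)[2] == 0.0

    def test_dM_does_not_depend_on_E(self, worked_params, rng):
        """The mutualist gains nothing directly from removing enemies."""
        H, M = 2.0, 1.5
        rates = {derivatives(State(H, E, M), worked_params)[2] for E in rng.uniform(0, 10, 10)}
        assert len(rates) == 1


def _host_eq_numeric(percap, lo=1e-8, hi=1e6):
    """Independent oracle: root of a per-capita growth function in H."""
    return brentq(percap, lo, hi, xtol=1e-14, rtol=1e-14)


class TestEquilibria:
    def test_host_eq_with_enemy_matches_root_finding(self, worked_params):
        p = worked_params
        expected = _host_eq_numeric(lambda H: p.gamma * p.b * H - p.delta_E)
        assert host_eq_with_enemy(p) == pytest.approx(expected, rel=1e-12)
        assert host_eq_with_enemy(p) == pytest.approx(1.0)
        assert host_eq_with_enemy(p.replace(b=2.0)) == pytest.approx(0.5)

    def test_host_eq_with_enemy_linear_in_delta_E(self, worked_params):
        doubled = worked_params.replace(delta_E=2 * worked_params.delta_E)
        assert host_eq_with_enemy(doubled) == pytest.approx(
            2 * host_eq_with_enemy(worked_params)
        )

    def test_host_eq_with_mutualist_matches_root_finding(self, worked_params):
        p = worked_params
        expected = _host_eq_numeric(
            lambda H: p.alpha * p.gamma * p.b * H - p.delta_M
        )
        assert host_eq_with_mutualist(p) == pytest.approx(expected, rel=1e-12)
        assert host_eq_with_mutualist(p) == pytest.approx(2.0)
        assert host_eq_with_mutualist(p.replace(alpha=2.0)) == pytest.approx(0.5)

    def test_identical_symbionts_have_identical_host_equilibria(self, worked_params):
        p = worked_params.replace(alpha=1.0)
        assert host_eq_with_mutualist(p) == pytest.approx(host_eq_with_enemy(p))

    def test_enemy_eq_density_against_full_fixed_point_solve(self, worked_params):
        p = worked_params

        def rhs2(x):
            H, E = x
            dH, dE, _ = derivatives(State(H, max(E, 0.0), 0.0), p)
            return [dH, dE]

        H_num, E_num = fsolve(rhs2, [0.5, 0.5], xtol=1e-13)
        assert enemy_eq_density(p) == pytest.approx(E_num, rel=1e-9)
        assert enemy_eq_density(p) == pytest.approx(0.6)
        assert enemy_eq_density(p.replace(r=2.0)) == pytest.approx(1.6)

    def test_enemy_eq_boundary_and_infeasibility(self, worked_params):
        p = worked_params
        q_bound = p.r * p.b * p.gamma / p.delta_E
        assert enemy_eq_density(p.replace(q=q_bound)) == pytest.approx(0.0)
        with pytest.raises(InfeasibleEquilibriumError):
            enemy_eq_density(p.replace(q=2 * q_bound))

    def test_mutualist_eq_density_against_full_fixed_point_solve(self, worked_params):
        p = worked_params

        def rhs2(x):
            H, M = x
            dH, _, dM = derivatives(State(H, 0.0, max(M, 0.0)), p)
            return [dH, dM]

        H_num, M_num = fsolve(rhs2, [1.5, 0.5], xtol=1e-13)
        assert mutualist_eq_density(p) == pytest.approx(M_num, rel=1e-9)
        assert mutualist_eq_density(p) == pytest.approx(0.4)

    def test_mutualist_eq_boundary_and_symmetry(self, worked_params):
        p = worked_params
        q_bound = p.r * p.b * p.alpha * p.gamma / p.delta_M
        assert mutualist_eq_density(p.replace(q=q_bound)) == pytest.approx(0.0)
        identical = p.replace(alpha=1.0)
        assert mutualist_eq_density(identical) == pytest.approx(
            enemy_eq_density(identical)
        )

    def test_equilibria_reports_infeasible_as_none(self, worked_params):
        p = worked_params.replace(q=10.0)  # kills both symbiont equilibria
        eq = equilibria(p)
        assert eq.E_star is None and eq.M_star is None
        assert eq.H_star_E is not None and eq.H_star_M is not None

    def test_equilibria_fixed_point_residuals(self, rng):
        for _ in range(100):
            p = random_params(rng)
            eq = equilibria(p)
            if eq.E_star is not None:
                res = derivatives(State(eq.H_star_E, eq.E_star, 0.0), p)
                assert max(abs(x) for x in res) < 1e-10
            if eq.M_star is not None:
                res = derivatives(State(eq.H_star_M, 0.0, eq.M_star), p)
                assert max(abs(x) for x in res) < 1e-10


class TestNetMutualism:
    def test_worked_values(self, worked_params):
        assert net_mutualism_U(worked_params) == pytest.approx(1.0)
        assert net_mutualism_U(worked_params.replace(alpha=2.0)) == pytest.approx(-0.5)
        assert net_mutualism_U(worked_params.replace(alpha=1.0)) == pytest.approx(0.0)

    def test_protection_examples(self, worked_params):
        assert is_net_protective(worked_params)
        assert not is_net_protective(worked_params.replace(alpha=1.0))
        assert not is_net_protective(
            worked_params.replace(alpha=0.9, delta_M=0.05)
        )

    def test_sign_consistency_over_random_draws(self, rng):
        """delta_M > alpha*delta_E agrees with U > 0 for 10,000 draws."""
        for _ in range(10_000):
            p = random_params(rng)
            assert is_net_protective(p) == (net_mutualism_U(p) > 0)

    rate = st.floats(min_value=1e-2, max_value=1e1)

    @settings(derandomize=True, max_examples=200)
    @given(b=rate, gamma=rate, alpha=rate, delta_E=rate, delta_M=rate)
    def test_U_is_invariant_to_r_q_u(self, b, gamma, alpha, delta_E, delta_M):
        """U compares the two one-symbiont host equilibria, which involve
        neither productivity, crowding, nor protection strength."""
        make = lambda r, q, u: ModelParams(
            r=r, q=q, b=b, gamma=gamma, alpha=alpha,
            delta_E=delta_E, delta_M=delta_M, u=u,
        )
        reference = net_mutualism_U(make(1.0, 0.4, 1.0))
        assert net_mutualism_U(make(7.0, 0.0, 0.2)) == pytest.approx(reference)
        assert is_net_protective(make(3.0, 2.0, 9.0)) == (reference > 0)


class TestInvasionRates:
    def test_enemy_invasion_closed_form(self, worked_params):
        # delta_M/alpha - delta_E - M*/u = 0.2 - 0.1 - 0.4 = -0.3
        assert enemy_invasion_rate(worked_params) == pytest.approx(-0.3)
        assert enemy_invasion_rate(worked_params.replace(u=0.1)) == pytest.approx(-3.9)

    def test_enemy_invasion_u_limit(self, worked_params):
        """As protection vanishes (u -> inf) only the mortality gap remains."""
        p = worked_params.replace(u=1e12)
        expected = p.delta_M / p.alpha - p.delta_E
        assert enemy_invasion_rate(p) == pytest.approx(expected, abs=1e-9)

    def test_enemy_invasion_requires_feasible_resident(self, worked_params):
        with pytest.raises(InfeasibleEquilibriumError):
            enemy_invasion_rate(worked_params.replace(q=10.0))

    def test_enemy_invasion_sign_matches_simulation(self, worked_params):
        """Linear rate sign agrees with the measured growth of a rare enemy."""
        from protmut.dynamics import SimulationOptions, integrate
        from protmut.model_core import (
            host_eq_with_mutualist,
            mutualist_eq_density,
        )

        for p in (worked_params, worked_params.replace(alpha=2.0, u=50.0)):
            H = host_eq_with_mutualist(p)
            M = mutualist_eq_density(p)
            opts = SimulationOptions(
                t_end=10.0, record_every=10.0, extinction_threshold=0.0
            )
            traj = integrate(State(H, M=M, E=1e-8), p, opts)
            measured = np.log(traj.col("E")[-1] / 1e-8) / 10.0
            assert np.sign(measured) == np.sign(enemy_invasion_rate(p))

    def test_mutualist_invasion_closed_form(self, worked_params):
        assert mutualist_invasion_rate(worked_params) == pytest.approx(-0.05)
        assert mutualist_invasion_rate(
            worked_params.replace(alpha=1.0)
        ) == pytest.approx(0.0)
        assert mutualist_invasion_rate(
            worked_params.replace(alpha=2.0)
        ) == pytest.approx(0.1)

    def test_no_invasion_from_rarity_theorem(self, rng):
        """A net-protective mutualist can never invade from rarity."""
        for _ in range(10_000):
            p = random_params(rng, require_feasible_enemy=True)
            assert not (mutualist_invasion_rate(p) > 0 and is_net_protective(p))


class TestInvasionThreshold:
    def test_worked_values(self, worked_params):
        assert analytic_m_star(worked_params) == pytest.approx(0.1)
        assert analytic_m_star(worked_params.replace(u=0.2)) == pytest.approx(0.02)
        assert analytic_m_star(worked_params.replace(alpha=1.0)) == pytest.approx(0.0)

    def test_zero_when_invasion_from_rarity_possible(self, worked_params):
        assert analytic_m_star(worked_params.replace(alpha=2.0)) == 0.0

    def test_clamped_growth_at_zero_equals_invasion_rate(self, worked_params):
        assert clamped_m_growth(worked_params, 0.0) == pytest.approx(
            mutualist_invasion_rate(worked_params)
        )

    def test_clamped_growth_vanishes_at_m_star(self, worked_params):
        m_star = analytic_m_star(worked_params)
        assert abs(clamped_m_growth(worked_params, m_star)) < 1e-10

    def test_clamped_growth_positive_above_m_star(self, worked_params):
        # the clamped (H, E) subsystem keeps a positive enemy only on a
        # finite window above m* (here m < 2/15); probe inside it
        m_star = analytic_m_star(worked_params)
        assert clamped_m_growth(worked_params, 1.2 * m_star) > 0

    def test_threshold_oracle_sign_change(self, rng):
        """sign(clamped growth at m) == sign(m - m*) around the threshold."""
        checked = 0
        for _ in range(200):
            p = random_params(
                rng, require_feasible_enemy=True, require_net_protective=True
            )
            m_star = analytic_m_star(p)
            for factor in (0.25, 0.5, 0.9, 1.1, 2.0, 4.0):
                m = factor * m_star
                try:
                    g = clamped_m_growth(p, m)
                except ClampedEnemyCollapseError:
                    continue
                assert np.sign(g) == np.sign(m - m_star)
                checked += 1
        assert checked > 100

    def test_clamped_enemy_collapse_flagged(self, worked_params):
        # enormous clamp drives the enemy out of the (H, E) subsystem
        with pytest.raises(ClampedEnemyCollapseError):
            clamped_m_growth(worked_params, 1e6)

    @pytest.mark.parametrize("param,direction", [("u", +1), ("alpha", -1)])
    def test_monotonicity(self, worked_params, param, direction):
        """m* rises with u (weak protection) and falls with virulence alpha."""
        grid = np.linspace(0.2, 0.9, 5)
        values = [
            analytic_m_star(worked_params.replace(**{param: x})) for x in grid
        ]
        diffs = np.diff(values) * direction
        assert np.all(diffs > 0)


class TestJacobian:
    def test_origin_is_diagonal(self, worked_params):
        p = worked_params
        J = jacobian(State(0.0, 0.0, 0.0), p)
        assert J == pytest.approx(np.diag([p.r, -p.delta_E, -p.delta_M]))

    def test_corner_entry_at_host_enemy_eq_is_mutualist_invasion_rate(
        self, worked_params
    ):
        H = host_eq_with_enemy(worked_params)
        E = enemy_eq_density(worked_params)
        J = jacobian(State(H, E, 0.0), worked_params)
        assert J[2, 2] == pytest.approx(mutualist_invasion_rate(worked_params))
        assert J[2, 0] == 0.0 and J[2, 1] == 0.0  # M = 0 row is decoupled

    def test_matches_central_differences(self, rng):
        for _ in range(20):
            p = random_params(rng)
            state = rng.uniform(0.1, 5.0, size=3)
            J = jacobian(State(*state), p)
            h = 1e-6
            for j in range(3):
                up = state.copy(); up[j] += h
                dn = state.copy(); dn[j] -= h
                fd = (
                    np.array(derivatives(State(*up), p))
                    - np.array(derivatives(State(*dn), p))
                ) / (2 * h)
                scale = np.maximum(np.abs(J[:, j]), 1.0)
                assert np.all(np.abs(J[:, j] - fd) / scale < 1e-6)


class TestHostEnemyStability:
    def test_worked_example_is_stable(self, worked_params):
        assert host_enemy_eq_is_stable(worked_params)

    def test_q_zero_is_neutral(self, worked_params):
        """Without self-limitation the linearization is a neutral center;
        the predicate reports it as not (asymptotically) stable."""
        assert not host_enemy_eq_is_stable(worked_params.replace(q=0.0))

    def test_infeasible_equilibrium_flagged(self, worked_params):
        with pytest.raises(InfeasibleEquilibriumError):
            host_enemy_eq_is_stable(worked_params.replace(q=10.0))

    def test_always_stable_for_random_feasible_draws(self, rng):
        """Any q > 0 stabilizes the host--enemy equilibrium."""
        for _ in range(1000):
            p = random_params(rng, require_feasible_enemy=True)
            assert host_enemy_eq_is_stable(p)
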