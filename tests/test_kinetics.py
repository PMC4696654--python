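"""Mass-action kinetics: rate-law evaluation, RK4 integration, conservation,
equilibrium detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import coopbind as cb
from coopbind.kinetics import rhs


# --------------------------------------------------------------------------
# Independent oracle: the five rate laws coded term by term, separately from
# the implementation, directly from the reaction scheme.
# --------------------------------------------------------------------------

def oracle_rhs(m00, m10, m01, m11, l, k1, k2, k1g2, k2g1,
               km1, km2, km1g2, km2g1):
    d_m00 = km1 * m10 + km2 * m01 - (k1 + k2) * l * m00
    d_m10 = k1 * l * m00 + km2g1 * m11 - (km1 + k2g1 * l) * m10
    d_m01 = k2 * l * m00 + km1g2 * m11 - (km2 + k1g2 * l) * m01
    d_m11 = (k1g2 * m01 + k2g1 * m10) * l - (km1g2 + km2g1) * m11
    d_l = (km1 * m10 + km2 * m01 + (km2g1 + km1g2) * m11
           - ((k1 + k2) * m00 + k2g1 * m10 + k1g2 * m01) * l)
    return np.array([d_m00, d_m10, d_m01, d_m11, d_l])


def coop_equilibrium_state(k_o, omega, m_total, l_free):
    """Closed-form equilibrium composition at a given free ligand."""
    x = k_o * l_free
    z = 1.0 + 2.0 * x + omega * x * x
    return cb.SystemState(t=0.0, m00=m_total / z,
                          m10=m_total * x / z, m01=m_total * x / z,
                          m11=m_total * omega * x * x / z, l=l_free)


class TestDerivatives:
    def test_hand_evaluated_unit_case(self, ident_rates):
        s = cb.SystemState(t=0, m00=1, m10=0, m01=0, m11=0, l=1)
        d = cb.derivatives(s, ident_rates)
        assert d == pytest.approx([-2.0, 1.0, 1.0, 0.0, -2.0])

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = rng.uniform(0.05, 20.0, size=8)
            rates = cb.RateConstants(*k, allow_cycle_violation=True)
            y = rng.uniform(0.0, 5.0, size=5)
            s = cb.SystemState(0.0, *y)
            np.testing.assert_allclose(cb.derivatives(s, rates),
                                       oracle_rhs(*y, *k), rtol=1e-12)

    def test_equilibrium_is_fixed_point(self):
        rates = cb.RateConstants.cooperative(2.0, 0.5)
        s = coop_equilibrium_state(2.0, 0.5, 1.0, 0.7)
        np.testing.assert_allclose(cb.derivatives(s, rates), 0.0,
                                   atol=1e-10)

    def test_conservation_combinations_vanish(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = rng.uniform(0.1, 10.0, size=8)
            y = rng.uniform(0.0, 3.0, size=5)
            d = rhs(y, k)
            assert abs(d[0] + d[1] + d[2] + d[3]) < 1e-12   # macromolecule
            assert abs(d[4] + d[1] + d[2] + 2 * d[3]) < 1e-12  # ligand


class TestRateConstants:
    def test_rejects_nonpositive(self):
        with pytest.raises(cb.KineticsError):
            cb.RateConstants(1, 1, 1, 1, 1, 1, 1, 0.0)
        with pytest.raises(cb.KineticsError):
            cb.RateConstants(-1, 1, 1, 1, 1, 1, 1, 1)

    def test_cycle_closure_enforced(self):
        with pytest.raises(cb.CycleClosureError):
            cb.RateConstants(1, 1, 5, 1, 1, 1, 1, 1)
        # override flag permits nonequilibrium schemes
        rc = cb.RateConstants(1, 1, 5, 1, 1, 1, 1, 1,
                              allow_cycle_violation=True)
        assert not rc.cycle_closed()

    @given(k_o=st.floats(1e-3, 1e3), omega=st.floats(1e-3, 1e3),
           off=st.floats(1e-2, 1e2))
    def test_constructors_close_the_cycle(self, k_o, omega, off):
        assert cb.RateConstants.cooperative(k_o, omega, off).cycle_closed()
        assert cb.RateConstants.two_different_sites(
            k_o, omega * k_o, off).cycle_closed()


class TestIntegration:
    def test_conservation_at_every_recorded_step(self, coop10_rates):
        tc = cb.simulate_binding(coop10_rates, 1.0, 10.0)
        m_tot = tc.states[:, :4].sum(axis=1)
        l_tot = tc.states[:, 4] + tc.states[:, 1] + tc.states[:, 2] \
            + 2 * tc.states[:, 3]
        np.testing.assert_allclose(m_tot, 1.0, rtol=1e-9)
        np.testing.assert_allclose(l_tot, 10.0, rtol=1e-9)

    def test_equilibrium_matches_closed_form(self, ident_rates):
        tc = cb.simulate_binding(ident_rates, 1.0, 10.0)
        eq = tc.equilibrium_state
        n_sim = cb.binding_density(eq, 1.0)
        n_cf = cb.IdenticalIndependent(1.0, 2).binding_density(eq.l)
        assert n_sim == pytest.approx(n_cf, rel=1e-4)

    def test_zero_ligand_is_constant(self, coop10_rates):
        tc = cb.simulate_binding(coop10_rates, 1.0, 0.0)
        assert tc.converged
        np.testing.assert_array_equal(tc.states[:, 4], 0.0)
        assert cb.binding_density(tc.equilibrium_state, 1.0) == 0.0

    def test_time_courses_monotone_to_equilibrium(self, coop10_rates):
        # the omega = 10 family approaches equilibrium monotonically in <n>
        for l0 in (0.1, 1.0, 10.0, 100.0):
            tc = cb.simulate_binding(coop10_rates, 1.0, l0)
            assert tc.converged
            assert np.all(np.diff(tc.n_avg) >= -1e-12)

    def test_step_halving_changes_equilibrium_below_1e6(self, coop10_rates):
        tc1 = cb.simulate_binding(coop10_rates, 1.0, 5.0)
        h = tc1.config.step_size
        cfg = cb.SimulationConfig(step_size=h / 2)
        tc2 = cb.simulate_binding(coop10_rates, 1.0, 5.0, cfg)
        n1 = cb.binding_density(tc1.equilibrium_state, 1.0)
        n2 = cb.binding_density(tc2.equilibrium_state, 1.0)
        assert n1 == pytest.approx(n2, rel=1e-6)

    def test_equilibrium_independent_of_initial_partitioning(self):
        rates = cb.RateConstants.cooperative(1.0, 0.5)
        std = cb.simulate_binding(rates, 1.0, 4.0)
        pre = cb.SystemState(t=0, m00=0.4, m10=0.3, m01=0.2, m11=0.1,
                             l=4.0 - 0.3 - 0.2 - 2 * 0.1)
        alt = cb.integrate(pre, rates)
        np.testing.assert_allclose(std.equilibrium_state.as_array(),
                                   alt.equilibrium_state.as_array(),
                                   rtol=1e-4)

    def test_matches_adaptive_reference_integrator(self, coop10_rates):
        # cross-check the fixed-step RK4 against scipy's adaptive solver
        from scipy.integrate import solve_ivp
        k = coop10_rates.as_array()
        sol = solve_ivp(lambda t, y: rhs(y, k), (0, 2.0),
                        [1.0, 0, 0, 0, 10.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        cfg = cb.SimulationConfig(max_time=2.0, convergence_threshold=1e-12)
        tc = cb.simulate_binding(coop10_rates, 1.0, 10.0, cfg)
        for i in (1, len(tc.times) // 2, len(tc.times) - 1):
            np.testing.assert_allclose(tc.states[i], sol.sol(tc.times[i]),
                                       rtol=1e-6, atol=1e-9)

    def test_nonconvergence_is_flagged_not_silent(self, ident_rates):
        cfg = cb.SimulationConfig(max_time=0.01)
        tc = cb.simulate_binding(ident_rates, 1.0, 1.0, cfg)
        assert not tc.converged

    def test_oversized_step_recovers_by_halving(self, ident_rates):
        cfg = cb.SimulationConfig(step_size=1.0)   # unstable at lambda ~ 12
        tc = cb.simulate_binding(ident_rates, 1.0, 10.0, cfg)
        assert tc.converged
        assert tc.config.step_size < 1.0
        n_cf = cb.IdenticalIndependent(1.0, 2).binding_density(
            tc.equilibrium_state.l)
        assert cb.binding_density(tc.equilibrium_state, 1.0) == \
            pytest.approx(n_cf, rel=1e-4)


class TestDetectEquilibrium:
    def test_constant_course_returns_first_state(self, coop10_rates):
        tc = cb.simulate_binding(coop10_rates, 1.0, 0.0)
        eq = cb.detect_equilibrium(tc)
        assert eq.t == tc.times[0]

    def test_returned_state_has_tiny_derivatives(self, coop10_rates):
        tc = cb.simulate_binding(coop10_rates, 1.0, 10.0)
        eq = cb.detect_equilibrium(tc)
        d = cb.derivatives(eq, coop10_rates)
        assert np.all(np.abs(d) < 1e-6)

    def test_zero_threshold_never_met(self, coop10_rates):
        tc = cb.simulate_binding(coop10_rates, 1.0, 10.0)
        with pytest.raises(cb.EquilibriumNotReachedError):
            cb.detect_equilibrium(tc, threshold=0.0)


class TestBindingDensity:
    def test_limiting_compositions(self):
        full = cb.SystemState(0, m00=0, m10=0, m01=0, m11=1.0, l=0)
        assert cb.binding_density(full, 1.0) == 2.0
        half = cb.SystemState(0, m00=0, m10=0.5, m01=0.5, m11=0, l=0)
        assert cb.binding_density(half, 1.0) == 1.0

    def test_two_forms_agree_on_simulated_states(self, coop10_rates):
        tc = cb.simulate_binding(coop10_rates, 1.0, 7.0)
        for i in range(0, len(tc.times), max(1, len(tc.times) // 5)):
            s = tc.state_at(i)
            direct = cb.binding_density(s, 1.0)
            from_conservation = (7.0 - s.l) / 1.0
            assert direct == pytest.approx(from_conservation, abs=1e-9)

    def test_rejects_nonpositive_m_total(self):
        s = cb.SystemState(0, 1, 0, 0, 0, 0)
        with pytest.raises(cb.KineticsError):
            cb.binding_density(s, 0.0)


class TestTimeCourseIO:
    def test_csv_round_trip_headers(self, ident_rates, tmp_path):
        tc = cb.simulate_binding(ident_rates, 1.0, 2.0)
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_s,m00_uM,m10_uM,m01_uM,m11_uM,l_uM,n_avg"
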