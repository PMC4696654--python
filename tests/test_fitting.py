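"""Pre-equilibrium discrimination, nonlinear fitting, model selection, and
exponential-phase classification."""

import numpy as np
import pytest

import coopbind as cb
from coopbind.fitting import predict_kinetics

M0 = 1.0
FIG6_GRID = [5.0, 10.0, 25.0, 50.0, 100.0, 300.0]


@pytest.fixture(scope="module")
def fig6_traces():
    return cb.paired_timecourses(0.55, 0.33058, FIG6_GRID, M0)


class TestPairedTimecourses:
    def test_degenerate_pair_has_zero_difference(self):
        traces = cb.paired_timecourses(1.0, 1.0, [1.0, 10.0], M0)
        for tr in traces:
            np.testing.assert_array_equal(tr.delta_n, 0.0)

    def test_positive_cooperativity_propagates_equivalence_error(self):
        with pytest.raises(cb.EquivalenceError):
            cb.paired_timecourses(1.0, 2.0, [1.0], M0)

    def test_traces_rise_to_interior_maximum_then_decay(self, fig6_traces):
        for tr in fig6_traces:
            assert tr.delta_n[0] == 0.0
            mag = np.abs(tr.delta_n)
            i = int(np.argmax(mag))
            assert 0 < i < mag.size - 1                  # interior peak
            assert tr.t_max == pytest.approx(tr.times[i])
            # single rise and fall (smoothed at trace resolution)
            assert np.all(np.diff(mag[: i + 1]) >= -1e-9)
            assert mag[-1] < 1e-4                        # equilibrated away

    def test_peak_time_decreases_with_ligand(self, fig6_traces):
        t_peaks = [tr.t_max for tr in fig6_traces]
        assert np.all(np.diff(t_peaks) < 0)

    def test_models_discriminable_before_equilibrium_only(self, fig6_traces):
        # equilibrium endpoints indistinguishable, pre-equilibrium not
        assert all(abs(tr.delta_n[-1]) < 1e-3 for tr in fig6_traces)
        assert max(abs(tr.delta_max) for tr in fig6_traces) > 0.01


class TestIsothermFitting:
    def test_noiseless_single_site_recovered_exactly(self):
        grid = np.logspace(-2, 2, 40)
        n = cb.SingleSite(2.5).binding_density(grid)
        fit = cb.fit_isotherm((grid, n), model="single_site")
        assert fit.converged
        assert fit.params["k_o"] == pytest.approx(2.5, rel=1e-6)
        assert fit.rss < 1e-16

    def test_full_range_fit_recovers_hidden_site_parameters(self):
        """Extending the ligand range to saturation recovers the generating
        omega and K_o of the strong-negative-cooperativity scenario."""
        iso = cb.preset_isotherm("fig7b")
        fit = cb.fit_isotherm(iso, model="cooperative")
        assert fit.params["k_o"] == pytest.approx(1.0, rel=0.05)
        assert fit.params["omega"] == pytest.approx(0.02, rel=0.05)

    @pytest.mark.parametrize("omega", [0.1, 0.33, 3.0, 10.0])
    def test_omega_recovered_from_noisy_isotherms(self, omega):
        """sigma = 0.02 noise: omega recovered within 15% in >= 95% of
        seeded replicates."""
        from coopbind.presets import _coop_grid
        grid = _coop_grid(1.0, omega, m_total=0.0)
        clean = cb.CooperativeTwoSite(1.0, omega).binding_density(grid)
        ok = 0
        n_rep = 40
        for seed in range(n_rep):
            noisy = cb.add_noise(clean, 0.02, 6000 + seed)
            fit = cb.fit_isotherm((grid, noisy), model="cooperative")
            ok += abs(fit.params["omega"] / omega - 1.0) <= 0.15
        assert ok >= 0.95 * n_rep

    def test_too_few_points_rejected(self):
        with pytest.raises(cb.FittingError):
            cb.fit_isotherm(([0.1, 1.0, 10.0], [0.1, 0.5, 0.9]),
                            model="hill")

    def test_unknown_model_rejected(self):
        with pytest.raises(cb.FittingError):
            cb.fit_isotherm(([0.1, 1.0], [0.1, 0.5]), model="langmuir")


class TestKineticFitting:
    K1M, K2M = 1.1, 0.1 / 1.1           # macroscopic constants of the pair
    TIMES = np.concatenate([[0.0], np.logspace(-2.3, 0.9, 35)])
    L_GRID = [5.0, 10.0, 25.0, 50.0]

    def observations(self, rates, noise=0.0, seed=0):
        obs = []
        for i, l0 in enumerate(self.L_GRID):
            n = predict_kinetics(rates, M0, l0, self.TIMES)
            if noise:
                n = cb.add_noise(n, noise, seed * 13 + i)
            obs.append((self.TIMES, n, l0))
        return obs

    def test_noiseless_self_fit_recovers_rates(self):
        two = cb.RateConstants.two_different_sites(1.0, 0.1)
        obs = self.observations(two)
        fit = cb.fit_kinetics(obs, "two_sites", (self.K1M, self.K2M), M0,
                              initial_off_rates={"km_site1": 0.5,
                                                 "km_site2": 2.0})
        assert fit.converged
        assert fit.params["km_site1"] == pytest.approx(1.0, rel=0.01)
        assert fit.params["km_site2"] == pytest.approx(1.0, rel=0.01)
        fitted = fit.extras["rates"]
        assert fitted.k1 == pytest.approx(two.k1, rel=0.01)
        assert fitted.k2 == pytest.approx(two.k2, rel=0.01)

    def test_constraints_hold_exactly_during_fit(self):
        two = cb.RateConstants.two_different_sites(1.0, 0.1)
        fit = cb.fit_kinetics(self.observations(two, 0.01, 3), "cooperative",
                              (self.K1M, self.K2M), M0)
        r = fit.extras["rates"]
        k_o = r.k1 / r.km1
        omega = (r.k2_given_1 / r.km2_given_1) / k_o
        assert 2 * k_o == pytest.approx(self.K1M, rel=1e-12)
        assert omega * k_o / 2 == pytest.approx(self.K2M, rel=1e-12)

    def test_generating_model_selected_in_90pct_of_replicates(self):
        """AICc picks the true (two-sites) model on noisy data."""
        two = cb.RateConstants.two_different_sites(1.0, 0.1)
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            obs = self.observations(two, noise=0.01, seed=100 + seed)
            f_two = cb.fit_kinetics(obs, "two_sites",
                                    (self.K1M, self.K2M), M0)
            f_coop = cb.fit_kinetics(obs, "cooperative",
                                     (self.K1M, self.K2M), M0)
            wins += cb.compare_fits(f_coop, f_two).model == "two_sites"
        assert wins >= 0.9 * n_rep

    def test_single_low_concentration_not_discriminable(self):
        """One low-[L]0 curve alone leaves the models statistically tied."""
        two = cb.RateConstants.two_different_sites(1.0, 0.1)
        times = np.linspace(0.0, 8.0, 30)
        n = cb.add_noise(predict_kinetics(two, M0, 1.0, times), 0.01, 77)
        obs = [(times, n, 1.0)]
        f_two = cb.fit_kinetics(obs, "two_sites", (self.K1M, self.K2M), M0)
        f_coop = cb.fit_kinetics(obs, "cooperative",
                                 (self.K1M, self.K2M), M0)
        assert abs(f_two.aicc - f_coop.aicc) < 2.0

    def test_infeasible_constraints_rejected(self):
        with pytest.raises(cb.FittingError, match="infeasible"):
            cb.fit_kinetics([(self.TIMES, self.TIMES * 0, 1.0)],
                            "two_sites", (1.0, 0.5), M0)


class TestClassifyKinetics:
    def test_exact_single_exponential(self):
        t = np.linspace(0, 5, 50)
        assert cb.classify_kinetics(t, 1.5 * (1 - np.exp(-1.3 * t))) == 1

    def test_hidden_site_low_ligand_is_monoexponential(self, hidden_rates):
        # pseudo-first-order conditions, low ligand: one apparent site
        t = np.linspace(0, 2.5, 40)
        n = predict_kinetics(hidden_rates, 0.1, 2.0, t)
        assert cb.classify_kinetics(t, cb.add_noise(n, 0.01, 5)) == 1

    def test_hidden_site_high_ligand_is_biexponential(self, hidden_rates):
        # very high ligand reveals the second (slower) binding phase
        t = np.concatenate([[0.0], np.logspace(-5, -1.5, 60)])
        n = predict_kinetics(hidden_rates, 1.0, 3.0e5, t)
        assert cb.classify_kinetics(t, cb.add_noise(n, 0.01, 5)) == 2

    def test_overshooting_trace_rejected(self):
        t = np.linspace(0, 5, 50)
        n = 1.0 - np.exp(-2 * t) * np.cos(3 * t)   # damped overshoot
        with pytest.raises(cb.FittingError, match="non-monotone"):
            cb.classify_kinetics(t, n)


class TestModelSelectionHelpers:
    def _fr(self, model, rss, n_obs, n_free):
        from coopbind.fitting import _aicc
        return cb.FitResult(model=model, params={}, stderr={}, rss=rss,
                            aicc=_aicc(rss, n_obs, n_free), converged=True,
                            n_obs=n_obs, n_free=n_free)

    def test_aicc_prefers_parsimony_at_equal_rss(self):
        a = self._fr("simple", 1.0, 50, 2)
        b = self._fr("complex", 1.0, 50, 4)
        assert cb.compare_fits(a, b).model == "simple"

    def test_ftest_requires_real_improvement(self):
        a = self._fr("simple", 1.0, 50, 2)
        b = self._fr("complex", 0.99, 50, 4)
        assert cb.compare_fits(a, b, method="ftest").model == "simple"
        c = self._fr("complex", 0.2, 50, 4)
        assert cb.compare_fits(a, c, method="ftest").model == "complex"

    def test_mismatched_data_rejected(self):
        with pytest.raises(cb.FittingError):
            cb.compare_fits(self._fr("a", 1, 50, 2), self._fr("b", 1, 40, 2))
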