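"""Subpopulation partition and P/N/G dynamics against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.stats import norm

from noisevolve import popdyn
from noisevolve.cytometry import ExpressionDistribution


class TestLogGaussianFit:
    def test_recovers_lognormal_parameters(self):
        rng = np.random.default_rng(0)
        n = 100_000
        vals = rng.lognormal(-2.0, 0.7, n)
        fit = popdyn.fit_log_gaussian(ExpressionDistribution(vals))
        assert abs(fit.mu - (-2.0)) < 3 * 0.7 / np.sqrt(n)
        assert abs(fit.sigma - 0.7) < 3 * 0.7 / np.sqrt(2 * n)

    def test_scaling_shifts_mu_only(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0.0, 0.5, 1000)
        f1 = popdyn.fit_log_gaussian(vals)
        f2 = popdyn.fit_log_gaussian(vals * 10.0)
        assert f2.mu - f1.mu == pytest.approx(np.log(10.0), rel=1e-9)
        assert f2.sigma == pytest.approx(f1.sigma, rel=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(popdyn.DegenerateFitError):
            popdyn.fit_log_gaussian(np.full(20, 3.0))

    def test_nonpositive_values_need_offset(self):
        vals = np.linspace(-0.5, 2.0, 30)
        with pytest.raises(ValueError):
            popdyn.fit_log_gaussian(vals)
        fit = popdyn.fit_log_gaussian(vals, offset=1.0)
        assert fit.sigma > 0


class TestKilledFraction:
    FIT = popdyn.LogNormalFit(mu=-1.5, sigma=0.6)

    def test_zero_dose_kills_nobody(self):
        tp = popdyn.KillThresholdParams(beta=0.5, K=20.0)
        assert popdyn.killed_fraction(self.FIT, tp, 0.0) == 0.0

    def test_threshold_at_median_kills_half(self):
        # choose dose so that beta * d/(K+d) = exp(mu)
        med = self.FIT.median
        beta, K = 2 * med, 30.0
        dose = K * med / (beta - med)
        tp = popdyn.KillThresholdParams(beta=beta, K=K)
        assert popdyn.killed_fraction(self.FIT, tp, dose) == pytest.approx(0.5)

    def test_monotone_in_dose(self):
        tp = popdyn.KillThresholdParams(beta=0.5, K=20.0)
        doses = np.linspace(0, 100, 40)
        vals = [popdyn.killed_fraction(self.FIT, tp, d) for d in doses]
        assert np.all(np.diff(vals) >= 0)

    def test_against_monte_carlo_oracle(self):
        """Closed form equals the brute-force lognormal-draw fraction
        within 3 binomial SEs on random parameter sets."""
        rng = np.random.default_rng(2)
        n = 200_000
        for _ in range(8):
            mu = rng.uniform(-3, 0)
            sigma = rng.uniform(0.2, 1.2)
            beta = rng.uniform(0.05, 1.0)
            K = rng.uniform(5, 80)
            dose = rng.uniform(0.5, 80)
            fit = popdyn.LogNormalFit(mu, sigma)
            tp = popdyn.KillThresholdParams(beta, K)
            a_d = popdyn.killed_fraction(fit, tp, dose)
            draws = rng.lognormal(mu, sigma, n)
            mc = np.mean(draws < tp.threshold(dose))
            se = np.sqrt(max(a_d * (1 - a_d), 1e-9) / n)
            assert abs(a_d - mc) < 3 * se + 1e-4

    def test_noise_effect_flips_with_threshold_side(self):
        """At matched medians the broader distribution loses more cells
        when the threshold is below the median and fewer when above —
        the distribution-level noise/stress trade-off."""
        lo = popdyn.LogNormalFit(mu=0.0, sigma=0.3)
        hi = popdyn.LogNormalFit(mu=0.0, sigma=0.9)
        tp = popdyn.KillThresholdParams(beta=10.0, K=10.0)
        dose_low = 1.0 / 9.0    # thres = 0.5 * beta * ... -> below median 1.0
        dose_high = 10.0        # thres = 5.0 -> above median
        assert tp.threshold(dose_low) < 1.0 < tp.threshold(dose_high)
        assert (popdyn.killed_fraction(hi, tp, dose_low)
                > popdyn.killed_fraction(lo, tp, dose_low))
        assert (popdyn.killed_fraction(hi, tp, dose_high)
                < popdyn.killed_fraction(lo, tp, dose_high))


class TestPersisterFraction:
    PP = popdyn.PersisterParams(mu_prime=np.log(20.0), sigma_prime=0.8)

    def test_peak_value_at_mu_prime(self):
        peak = popdyn.persister_fraction(self.PP, 20.0)
        assert peak == pytest.approx(1 / (np.sqrt(2 * np.pi) * 0.8))

    def test_vanishes_at_extreme_dose(self):
        assert popdyn.persister_fraction(self.PP, 1e9) < 1e-12
        assert popdyn.persister_fraction(self.PP, 0.0) == 0.0

    def test_halving_sigma_doubles_peak(self):
        narrow = popdyn.PersisterParams(np.log(20.0), 0.4)
        assert popdyn.persister_fraction(narrow, 20.0) == pytest.approx(
            2 * popdyn.persister_fraction(self.PP, 20.0))

    def test_jacobian_variant(self):
        assert popdyn.persister_fraction(self.PP, 20.0, jacobian=True) == \
            pytest.approx(popdyn.persister_fraction(self.PP, 20.0) / 20.0)


class TestInitialFractions:
    def test_zero_dose_all_nongenetic(self):
        fr = popdyn.initial_fractions(
            popdyn.LogNormalFit(-1.5, 0.5),
            popdyn.KillThresholdParams(0.5, 20.0),
            popdyn.PersisterParams(np.log(20.0), 0.8), 0.0)
        assert (fr.a_d, fr.a_p, fr.a_n) == (0.0, 0.0, 1.0)

    def test_extreme_dose_survivors_all_persisters(self):
        fit = popdyn.LogNormalFit(0.0, 0.5)
        tp = popdyn.KillThresholdParams(beta=float(np.exp(8.0)), K=1.0)
        pp = popdyn.PersisterParams(np.log(100.0), 1.0)
        with pytest.warns(UserWarning, match="clipping"):
            fr = popdyn.initial_fractions(fit, tp, pp, 100.0)
        assert fr.a_d > 0.99
        assert fr.a_n == 0.0
        assert fr.a_p == pytest.approx(1.0 - fr.a_d)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-3, 1), st.floats(0.1, 1.5), st.floats(0.05, 1.0),
           st.floats(5, 100), st.floats(0, 4), st.floats(0.2, 2.0),
           st.floats(0, 100))
    def test_fractions_always_sum_to_one(self, mu, sigma, beta, K,
                                         mu_p, sigma_p, dose):
        fr = popdyn.initial_fractions(
            popdyn.LogNormalFit(mu, sigma),
            popdyn.KillThresholdParams(beta, K),
            popdyn.PersisterParams(mu_p, sigma_p), dose)
        assert abs(fr.a_d + fr.a_p + fr.a_n - 1.0) <= 1e-12
        assert 0 <= fr.a_d <= 1 and 0 <= fr.a_p <= 1 and 0 <= fr.a_n <= 1


FRACS = popdyn.SubpopulationFractions(0.3, 0.2, 0.5)
RATES = popdyn.RateSet(r_pn=0.05, r_np=0.02, r_gp=0.01, r_gn=0.005,
                       k_n=0.4, k_g=0.5, g_n=0.3, g_g=0.05)


class TestODE:
    def test_matches_matrix_exponential(self):
        """Linear-system trajectory equals the expm closed form."""
        traj = popdyn.integrate_ode(FRACS, RATES, 1000.0, 10.0, dt=0.5)
        y0 = np.array([200.0, 500.0, 0.0])
        exact = np.array([expm(RATES.matrix() * t) @ y0 for t in traj.t])
        ours = np.stack([traj.p, traj.n, traj.g], axis=1)
        assert np.max(np.abs(ours - exact) / np.maximum(exact, 1e-9)) < 1e-8

    def test_zero_rates_keep_population_constant(self):
        traj = popdyn.integrate_ode(FRACS, popdyn.RateSet(), 1000.0, 5.0)
        # FRACS = (a_d=0.3, a_p=0.2, a_n=0.5): P0 = 200, N0 = 500
        assert np.allclose(traj.p, 200.0) and np.allclose(traj.n, 500.0)
        assert np.allclose(traj.g, 0.0)

    def test_decoupled_decay_to_extinction(self):
        rates = popdyn.RateSet(k_n=0.1, g_n=0.6)
        fr = popdyn.SubpopulationFractions(0.0, 0.0, 1.0)
        traj = popdyn.integrate_ode(fr, rates, 1000.0, 20.0)
        assert np.allclose(traj.n, 1000.0 * np.exp(-0.5 * traj.t), rtol=1e-6)
        assert traj.n[-1] < 0.05 * 1000.0

    def test_conservation_identity(self):
        """Switching terms cancel: column sums of the generator are
        (0, k_N - g_N, k_G - g_G), i.e. d(P+N+G)/dt = k_N N + k_G G
        - g_N N - g_G G."""
        col_sums = RATES.matrix().sum(axis=0)
        assert col_sums == pytest.approx(
            [0.0, RATES.k_n - RATES.g_n, RATES.k_g - RATES.g_g])

    def test_capacity_saturates_total(self):
        rates = popdyn.RateSet(k_n=0.8, g_n=0.1)
        fr = popdyn.SubpopulationFractions(0.0, 0.0, 1.0)
        traj = popdyn.integrate_ode(fr, rates, 500.0, 40.0, capacity=5000.0)
        assert traj.n_tot[-1] == pytest.approx(5000.0, rel=0.01)


class TestSSA:
    def test_zero_rates_constant_trajectory(self):
        traj = popdyn.simulate_stochastic(FRACS, popdyn.RateSet(), 1000.0,
                                          5.0, seed=0)
        assert np.all(traj.p == 200) and np.all(traj.n == 500)

    def test_yule_process_mean(self):
        """Pure birth from 100 founders: mean size after t=1 is 100 e^k."""
        fr = popdyn.SubpopulationFractions(0.0, 0.0, 1.0)
        rates = popdyn.RateSet(k_n=1.0)
        finals = np.array([
            popdyn.simulate_stochastic(fr, rates, 100.0, 1.0, seed=s).n[-1]
            for s in range(500)])
        expected = 100 * np.exp(1.0)
        # Yule variance: n0 e^{kt} (e^{kt} - 1)
        se = np.sqrt(100 * np.exp(1.0) * (np.exp(1.0) - 1) / 500)
        assert abs(finals.mean() - expected) < 3 * se

    def test_ensemble_mean_matches_ode(self):
        """Stochastic ensemble mean agrees with the deterministic solution
        within 3 SEs for each subpopulation."""
        n_runs = 200
        runs = [popdyn.simulate_stochastic(FRACS, RATES, 1000.0, 2.0, seed=s,
                                           record_dt=2.0)
                for s in range(n_runs)]
        finals = np.array([[r.p[-1], r.n[-1], r.g[-1]] for r in runs])
        ode = popdyn.integrate_ode(FRACS, RATES, 1000.0, 2.0, dt=2.0)
        target = np.array([ode.p[-1], ode.n[-1], ode.g[-1]])
        se = finals.std(axis=0, ddof=1) / np.sqrt(n_runs)
        assert np.all(np.abs(finals.mean(axis=0) - target) < 3 * se + 0.5)

    def test_seed_determinism(self):
        a = popdyn.simulate_stochastic(FRACS, RATES, 500.0, 3.0, seed=9)
        b = popdyn.simulate_stochastic(FRACS, RATES, 500.0, 3.0, seed=9)
        assert np.array_equal(a.n_tot, b.n_tot)

    def test_tau_leaping_agrees_with_exact_mean(self):
        """Hybrid tau-leap runs match exact-SSA ensemble means for a large
        population."""
        fr = popdyn.SubpopulationFractions(0.0, 0.1, 0.9)
        rates = popdyn.RateSet(k_n=0.5, g_n=0.1)
        kw = dict(n0=20_000.0, t_max=2.0, record_dt=2.0)
        leap = np.array([popdyn.simulate_stochastic(fr, rates, seed=s, **kw).n[-1]
                         for s in range(40)])
        exact = np.array([popdyn.simulate_stochastic(
            fr, rates, seed=1000 + s, leap_threshold=np.inf, **kw).n[-1]
            for s in range(40)])
        se = np.sqrt(leap.var(ddof=1) / 40 + exact.var(ddof=1) / 40)
        assert abs(leap.mean() - exact.mean()) < 4 * se


class TestScanRates:
    def _fracs(self):
        # delayed-adaptation regime: most survivors are persisters
        return {22.5: popdyn.SubpopulationFractions(0.55, 0.40, 0.05)}

    def test_no_p_to_g_conversion_grows_immediately(self):
        """With a_n > 0 and k_n > g_n, the family without P->G conversion
        shows immediate (though slow) growth, never delayed adaptation."""
        base = popdyn.RateSet(r_pn=0.002, r_np=0.001, r_gp=0.002, r_gn=5e-4,
                              k_n=0.8, k_g=0.8, g_n=0.45, g_g=0.05)
        table = popdyn.scan_rates(base, self._fracs(), span_decades=2,
                                  points_per_decade=1, scanned=("r_gp",))
        zero_family = table[table["r_gp_zero"]]
        assert len(zero_family) == 1
        assert set(zero_family["class"]) == {"immediate_growth"}

    def test_extinction_class_without_rescue(self):
        base = popdyn.RateSet(k_n=0.3, g_n=1.5)
        fracs = {50.0: popdyn.SubpopulationFractions(0.6, 0.0, 0.4)}
        table = popdyn.scan_rates(base, fracs, span_decades=1,
                                  scanned=("r_np",), include_zero=True)
        assert set(table["class"]) == {"extinction"}

    def test_delayed_adaptation_when_n_declines_and_g_rescues(self):
        base = popdyn.RateSet(r_pn=0.002, r_np=0.002, r_gp=0.005, r_gn=5e-4,
                              k_n=0.8, k_g=0.8, g_n=1.2, g_g=0.05)
        fracs = {35.0: popdyn.SubpopulationFractions(0.5, 0.45, 0.05)}
        table = popdyn.scan_rates(base, fracs, span_decades=1,
                                  scanned=("r_gp",), include_zero=False)
        assert "delayed_adaptation" in set(table["class"])
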