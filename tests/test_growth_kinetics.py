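"""Kinetic fits must recover noiseless data exactly, match brute-force
oracles on noisy data, and respect the fitting-window rules."""

import dataclasses
import warnings

import numpy as np
import pytest

from acetoflux.growth_kinetics import (
    GrowthCurve,
    GrowthFit,
    KineticsError,
    compute_yield,
    fit_exponential_growth,
    fit_uptake_secretion,
    mean_2sem,
    to_specific_rate,
)
from acetoflux.synthetic_data import SimulationConfig, simulate_growth_experiment


def _curve(times, od, **kw):
    return GrowthCurve(times=np.asarray(times), od=np.asarray(od), **kw)


class TestExponentialFit:
    def test_noiseless_data_recovered_exactly(self):
        t = np.arange(0, 3.01, 0.5)
        curve = _curve(t, 0.02 * np.exp(0.7 * t))
        fit = fit_exponential_growth(curve)
        assert fit.mu == pytest.approx(0.7, abs=1e-6)
        assert fit.B0 == pytest.approx(0.02, abs=1e-8)
        assert fit.sse < 1e-16
        assert fit.exponential_ok

    def test_constant_series_gives_zero_rate(self):
        t = np.arange(0, 3.01, 0.5)
        fit = fit_exponential_growth(_curve(t, np.full_like(t, 0.3)))
        assert fit.mu == pytest.approx(0.0, abs=1e-8)

    def test_noisy_optimum_matches_grid_search_oracle(self):
        """The NLS optimum must not be beaten by a brute-force scan of mu
        with B0 profiled out analytically."""
        rng = np.random.default_rng(4)
        t = np.linspace(0, 3.5, 8)
        y = 0.05 * np.exp(0.62 * t) + rng.normal(0, 0.01, t.size)
        fit = fit_exponential_growth(_curve(t, y), r2_threshold=0.0)

        def sse(mu):
            e = np.exp(mu * t)
            b0 = (y @ e) / (e @ e)
            return np.sum((y - b0 * e) ** 2)

        grid = np.linspace(0.3, 0.9, 2001)
        best = min(sse(m) for m in grid)
        assert sse(fit.mu) <= best + 1e-12

    def test_window_excludes_od_above_ceiling(self):
        t = np.arange(0, 8.01, 0.5)
        od = 0.02 * np.exp(0.7 * t)
        fit = fit_exponential_growth(_curve(t, od), od_ceiling=1.0)
        assert od[np.searchsorted(t, fit.fit_window[1], side="right")] >= 1.0 or \
            fit.fit_window[1] == t[-1]
        assert 0.02 * np.exp(0.7 * fit.fit_window[1]) < 1.0

    def test_window_starts_at_addition_time(self):
        """For treated cultures only post-addition points are fitted, so a
        growth-rate switch at the addition is recovered."""
        cfg = SimulationConfig(
            od_noise_sd=0.0, conc_noise_sd=0.0, replicate_cv=0.0, n_replicates=1,
            acetate_add_time=1.5, acetate_added_mM=128.0, mu_after=0.31,
        )
        rep = simulate_growth_experiment(cfg).replicates[0]
        fit = fit_exponential_growth(rep.curve)
        assert fit.fit_window[0] >= 1.5
        assert fit.mu == pytest.approx(0.31, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(KineticsError):
            fit_exponential_growth(_curve([0, 1, 2], [0.1, 1.5, 2.0]), od_ceiling=1.0)

    def test_nonexponential_data_flagged(self):
        t = np.arange(0, 3.01, 0.25)
        od = 0.05 + 0.2 * t  # linear, not exponential
        with pytest.warns(UserWarning, match="exponentiality"):
            fit = fit_exponential_growth(_curve(t, od))
        assert not fit.exponential_ok


class TestUptakeSecretionFit:
    def test_noiseless_joint_fit_recovers_yield_and_rate(self, noiseless_config):
        # grid stops before glucose exhaustion so the closed form holds
        # at every fitted point
        cfg = dataclasses.replace(noiseless_config, yield_true=0.01,
                                  t_grid=np.arange(0, 2.26, 0.25))
        rep = simulate_growth_experiment(cfg).replicates[0]
        rf = fit_uptake_secretion(
            (rep.curve.times, rep.metabolites["glucose"]), rep.curve, mode="uptake"
        )
        assert rf.yield_Y == pytest.approx(0.01, abs=1e-8)
        assert rf.rate == pytest.approx(60.0, abs=1e-4)  # r_glc = mu / Y
        assert rf.C0 == pytest.approx(16.65, abs=1e-6)
        assert rf.mu_used == pytest.approx(0.6, abs=1e-8)

    def test_joint_mu_matches_od_only_mu_on_consistent_data(self, noiseless_config):
        rep = simulate_growth_experiment(noiseless_config).replicates[0]
        od_fit = fit_exponential_growth(rep.curve)
        rf = fit_uptake_secretion(
            (rep.curve.times, rep.metabolites["glucose"]), rep.curve, mode="uptake"
        )
        assert rf.mu_used == pytest.approx(od_fit.mu, abs=1e-7)

    def test_fitted_glucose_curve_monotone_decreasing(self, noiseless_config):
        rep = simulate_growth_experiment(noiseless_config).replicates[0]
        rf = fit_uptake_secretion(
            (rep.curve.times, rep.metabolites["glucose"]), rep.curve, mode="uptake"
        )
        t = rep.curve.times
        model = rf.C0 - (rf.B0_used / rf.yield_Y) * (np.exp(rf.mu_used * t) - 1.0)
        assert np.all(np.diff(model) < 0)

    def test_yield_identity_with_compute_yield(self, noiseless_config):
        rep = simulate_growth_experiment(noiseless_config).replicates[0]
        rf = fit_uptake_secretion(
            (rep.curve.times, rep.metabolites["glucose"]), rep.curve, mode="uptake"
        )
        assert compute_yield(rf.mu_used, rf.rate) == pytest.approx(rf.yield_Y, rel=1e-9)

    def test_noiseless_secretion_rate_recovered(self, noiseless_config):
        cfg = dataclasses.replace(
            noiseless_config, secretion_rates_true={"acetate": 1.7}
        )
        rep = simulate_growth_experiment(cfg).replicates[0]
        gfit = fit_exponential_growth(rep.curve)
        rf = fit_uptake_secretion(
            (rep.curve.times, rep.metabolites["acetate"]), gfit,
            mode="secretion", metabolite="acetate",
        )
        assert rf.rate == pytest.approx(1.7, abs=1e-7)
        assert rf.C0 == pytest.approx(0.0, abs=1e-9)

    def test_flat_product_series_gives_zero_rate(self):
        gfit = GrowthFit(mu=0.6, B0=0.05, fit_window=(0, 3), sse=0.0, n_points=7)
        t = np.arange(0, 3.01, 0.5)
        rf = fit_uptake_secretion((t, np.full_like(t, 2.5)), gfit, mode="secretion")
        assert rf.rate == pytest.approx(0.0, abs=1e-10)
        assert rf.C0 == pytest.approx(2.5, abs=1e-10)

    def test_all_zero_glucose_rejected(self, noiseless_config):
        rep = simulate_growth_experiment(noiseless_config).replicates[0]
        with pytest.raises(KineticsError):
            fit_uptake_secretion(
                (rep.curve.times, np.zeros_like(rep.curve.times)),
                rep.curve, mode="uptake",
            )

    def test_unbiased_over_seeded_noisy_replicates(self):
        """Monte Carlo: 200 noisy replicates; the mean fitted rate lies
        within 2 SEM of the generative truth."""
        cfg = SimulationConfig(n_replicates=1, replicate_cv=0.0)
        rates, mus = [], []
        rng = np.random.default_rng(17)
        for _ in range(200):
            rep = simulate_growth_experiment(
                dataclasses.replace(cfg, seed=int(rng.integers(2**31 - 1)))
            ).replicates[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                rf = fit_uptake_secretion(
                    (rep.curve.times, rep.metabolites["glucose"]),
                    rep.curve, mode="uptake",
                )
            rates.append(rf.rate)
            mus.append(rf.mu_used)
        r_true = cfg.mu_true / cfg.yield_true
        m, two_sem = mean_2sem(rates)
        assert abs(m - r_true) <= two_sem
        m, two_sem = mean_2sem(mus)
        assert abs(m - cfg.mu_true) <= two_sem


class TestUnitHelpers:
    @pytest.mark.parametrize("mu,r,expected", [(0.6, 6.0, 0.1), (0.0, 3.0, 0.0)])
    def test_yield_ratio(self, mu, r, expected):
        assert compute_yield(mu, r) == pytest.approx(expected)

    def test_yield_rejects_nonpositive_uptake(self):
        with pytest.raises(KineticsError):
            compute_yield(0.6, 0.0)

    def test_specific_rate_conversion_and_round_trip(self):
        assert to_specific_rate(4.7, 0.47) == pytest.approx(10.0)
        assert to_specific_rate(3.3, 1.0) == pytest.approx(3.3)
        assert to_specific_rate(to_specific_rate(2.2, 0.47), 1 / 0.47) == pytest.approx(2.2)
        with pytest.raises(KineticsError):
            to_specific_rate(1.0, 0.0)

    def test_mean_2sem(self):
        m, s = mean_2sem([1.0, 2.0, 3.0])
        assert m == pytest.approx(2.0)
        assert s == pytest.approx(2.0 * 1.0 / np.sqrt(3))
        with pytest.raises(KineticsError):
            mean_2sem([])
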