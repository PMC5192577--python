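"""Two-state H1 binding kinetics: rate algebra, FRAP/CP fits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from chromodyn import binding as bind
from chromodyn import synthetic
from chromodyn.binding import (
    BindingParams,
    FrapProfileSeries,
    cp_model,
    fit_cp,
    fit_point_frap,
    fit_recovery,
    fit_strip_profiles,
    recovery_model,
    residence_times,
    steady_state_rates,
)

HET = dict(f_free=0.06, f_short=0.18, f_long=0.76, k_off1=1.05, k_off2=8e-3)
EU = dict(f_free=0.06, f_short=0.31, f_long=0.63, k_off1=0.76, k_off2=8e-3)


class TestSteadyState:
    def test_heterochromatin_rates(self):
        k_on, k_switch = steady_state_rates(**{k: HET[k] for k in
                                               ("f_free", "f_short", "f_long", "k_off1", "k_off2")})
        assert k_on == pytest.approx(3.3, abs=0.1)
        assert k_switch == pytest.approx(3.4e-2, abs=0.2e-2)

    def test_euchromatin_rates(self):
        k_on, k_switch = steady_state_rates(**{k: EU[k] for k in
                                               ("f_free", "f_short", "f_long", "k_off1", "k_off2")})
        assert k_on == pytest.approx(4.0, abs=0.1)
        assert k_switch == pytest.approx(1.6e-2, abs=0.1e-2)

    def test_no_long_state(self):
        k_on, k_switch = steady_state_rates(0.2, 0.8, 0.0, 1.0, 0.01)
        assert k_switch == 0.0

    def test_rejects_zero_fractions(self):
        with pytest.raises(ValueError):
            steady_state_rates(0.0, 0.5, 0.5, 1.0, 0.01)

    @pytest.mark.parametrize("params", [HET, EU])
    def test_stationarity_against_ode_integration(self, params):
        """Plugging the closed rates back into the kinetic ODEs must leave
        the fractions stationary (independent ODE-integration oracle)."""
        f = (params["f_free"], params["f_short"], params["f_long"])
        k_on, k_switch = steady_state_rates(*f, params["k_off1"], params["k_off2"])
        k1, k2 = params["k_off1"], params["k_off2"]

        def rhs(_, y):
            free, short, long_ = y
            return [
                k1 * short + k2 * long_ - k_on * free,
                k_on * free - (k1 + k_switch) * short,
                k_switch * short - k2 * long_,
            ]

        deriv0 = np.array(rhs(0.0, f))
        assert np.all(np.abs(deriv0) < 1e-10)
        sol = solve_ivp(rhs, (0.0, 500.0), f, rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], f, atol=1e-8)


class TestResidenceTimes:
    def test_printed_values(self):
        p = BindingParams(0.06, 0.18, 0.76, k_off1=1.05, k_switch=0.033, k_off2=8.8e-3)
        t_short, t_long, _ = residence_times(p)
        assert t_short == pytest.approx(0.95, abs=0.01)  # ~1 s
        assert t_long == pytest.approx(114.0, abs=1.0)  # ~2 min

    def test_mean_untreated_is_about_4s(self):
        t_means = []
        for c in (HET, EU):
            f = (c["f_free"], c["f_short"], c["f_long"])
            k_on, k_switch = steady_state_rates(*f, c["k_off1"], c["k_off2"])
            p = BindingParams(*f, k_on=k_on, k_off1=c["k_off1"],
                              k_switch=k_switch, k_off2=c["k_off2"])
            t_means.append(residence_times(p)[2])
        assert np.mean(t_means) == pytest.approx(4.0, rel=0.25)

    def test_limits_in_k_switch(self):
        base = dict(k_off1=1.0, k_off2=0.01)
        p0 = BindingParams(0.1, 0.5, 0.4, k_switch=1e-9, **base)
        assert residence_times(p0)[2] == pytest.approx(1.0, rel=1e-6)
        p_inf = BindingParams(0.1, 0.5, 0.4, k_switch=1e6, **base)
        t_mean = residence_times(p_inf)[2]
        assert t_mean == pytest.approx(1.0 / 0.01, rel=1e-3)

    def test_mean_absorption_time_vs_stochastic_simulation(self):
        """Monte Carlo of the short->long->free jump process reproduces
        the closed-form mean bound time."""
        rng = np.random.default_rng(7)
        k1, ks, k2 = 1.05, 0.033, 8.8e-3
        n = 400000
        leave_short = rng.exponential(1.0 / (k1 + ks), n)
        goes_long = rng.random(n) < ks / (k1 + ks)
        total = leave_short + np.where(goes_long, rng.exponential(1.0 / k2, n), 0.0)
        p = BindingParams(0.06, 0.18, 0.76, k_off1=k1, k_switch=ks, k_off2=k2)
        assert total.mean() == pytest.approx(residence_times(p)[2], rel=0.03)


class TestStripProfiles:
    def test_noiseless_slope_is_2D(self):
        times = np.linspace(0.0, 60.0, 12)
        x = np.linspace(-6.0, 6.0, 101)
        series, _ = synthetic.simulate_frap_profiles(
            D_app=0.01, sigma0=1.0, h=1.0, times=times, positions=x, noise_sd=0.0, seed=0
        )
        fit = fit_strip_profiles(series)
        assert fit.D_app == pytest.approx(0.01, rel=1e-5)
        assert fit.sigma0 == pytest.approx(1.0, rel=1e-4)

    def test_zero_diffusion_flat_widths(self):
        times = np.linspace(0.0, 60.0, 10)
        x = np.linspace(-6.0, 6.0, 101)
        series, _ = synthetic.simulate_frap_profiles(
            D_app=0.0, sigma0=1.2, h=1.0, times=times, positions=x, noise_sd=0.0, seed=0
        )
        fit = fit_strip_profiles(series)
        assert fit.D_app == pytest.approx(0.0, abs=1e-9)

    def test_requires_five_points(self):
        x = np.linspace(-3, 3, 31)
        series = FrapProfileSeries(
            times=np.arange(3.0), positions=x, profiles=np.ones((3, 31)), h=1.0
        )
        with pytest.raises(ValueError):
            fit_strip_profiles(series)

    def test_ci_covers_truth(self):
        """Regression CI covers the true D_app in >= 90 % of seeded runs."""
        times = np.linspace(0.0, 120.0, 15)
        x = np.linspace(-6.0, 6.0, 121)
        hits = 0
        n_runs = 60
        for seed in range(n_runs):
            series, _ = synthetic.simulate_frap_profiles(
                D_app=0.01, sigma0=1.0, h=1.0, times=times, positions=x,
                noise_sd=0.01, seed=seed,
            )
            fit = fit_strip_profiles(series)
            lo, hi = fit.D_app_ci
            hits += lo <= 0.01 <= hi
        assert hits / n_runs >= 0.90


class TestRecovery:
    def test_all_free_is_flat(self):
        t = np.linspace(0.0, 100.0, 50)
        F = recovery_model(t, 1.0, 0.0, 0.0, 0.01, 0.01, h=1.0, sigma0=1.0)
        assert np.allclose(F, 1.0)

    def test_noiseless_self_consistency(self):
        t = np.linspace(0.0, 600.0, 240)
        p = BindingParams(0.06, 0.31, 0.63, k_off2=8.8e-3)
        curve, truth = synthetic.simulate_recovery(
            p, D_app=0.01, h=1.0, sigma0=0.8, times=t, noise_sd=0.0, seed=0
        )
        out = fit_recovery(t, curve, h=1.0, sigma0=0.8)
        assert out.params["f_slow"].value == pytest.approx(truth["f_slow"], rel=1e-4)
        assert out.params["k_off2"].value == pytest.approx(truth["k_off2"], rel=1e-4)
        assert out.params["f_free"].value == pytest.approx(truth["f_free"], abs=1e-4)

    def test_noisy_recovery_of_printed_values(self):
        """f_free = 6 % and k_off2 = 8.8e-3 1/s both recovered within 20 %."""
        t = np.linspace(0.0, 600.0, 300)
        p = BindingParams(0.06, 0.31, 0.63, k_off2=8.8e-3)
        rec_free, rec_koff = [], []
        for seed in range(5):
            curve, _ = synthetic.simulate_recovery(
                p, D_app=0.01, h=1.0, sigma0=0.8, times=t,
                noise_sd=0.004, seed=seed,
            )
            out = fit_recovery(t, curve, h=1.0, sigma0=0.8)
            rec_free.append(out.params["f_free"].value)
            rec_koff.append(out.params["k_off2"].value)
        assert np.mean(rec_free) == pytest.approx(0.06, rel=0.20)
        assert np.mean(rec_koff) == pytest.approx(8.8e-3, rel=0.20)


class TestCp:
    def test_no_bleaching_is_flat(self):
        t = np.linspace(0.0, 100.0, 60)
        y = cp_model(t, 0.1, 0.3, 0.6, 1.0, 0.01, k_b=0.0)
        assert np.allclose(y, 1.0)

    def test_long_time_asymptote(self):
        t = np.array([1e7])
        f_free, f1, f2, k1, k2, kb = 0.1, 0.3, 0.6, 1.0, 0.01, 0.05
        y = cp_model(t, f_free, f1, f2, k1, k2, kb)
        expected = f_free + f1 * k1 / (k1 + kb) + f2 * k2 / (k2 + kb)
        assert y[0] == pytest.approx(expected, rel=1e-9)

    def test_recovers_fast_off_rate(self):
        """Heterochromatin-like CP data: k_off1 = 1.05 1/s within 20 %."""
        t = np.linspace(0.0, 300.0, 3001)  # 0.1-s sampling resolves the fast state
        p = BindingParams(0.06, 0.18, 0.76, k_off1=1.05, k_off2=8e-3)
        rec = []
        for seed in range(5):
            curve, _ = synthetic.simulate_cp(p, k_b=0.5, times=t, noise_sd=0.003, seed=seed)
            out = fit_cp(curve.times, curve.intensity, k_b=0.5)
            k_offs = sorted([out.params["k_off1"].value, out.params["k_off2"].value])
            rec.append(k_offs[-1])
        assert np.mean(rec) == pytest.approx(1.05, rel=0.20)


class TestPointFrap:
    def test_requires_three_curves(self):
        t = np.linspace(0, 10, 20)
        with pytest.raises(ValueError):
            fit_point_frap([(t, np.ones_like(t))] * 2)

    def test_shared_rates_recovered(self):
        """Rates (0.83, 8.2e-3) shared across bleach durations, within 25 %."""
        t = np.linspace(0.0, 600.0, 500)
        curves, truth = synthetic.simulate_point_frap(
            k_off1=0.83, k_off2=8.2e-3, bleach_durations=[0.1, 0.4, 1.2, 3.0],
            times=t, noise_sd=0.004, seed=3,
        )
        out = fit_point_frap(curves)
        ks = sorted([out.params["k1"].value, out.params["k2"].value])
        assert ks[1] == pytest.approx(0.83, rel=0.25)
        assert ks[0] == pytest.approx(8.2e-3, rel=0.25)

    def test_flat_curve_handled(self):
        t = np.linspace(0.0, 10.0, 50)
        curves = [(t, np.ones_like(t)) for _ in range(3)]
        out = fit_point_frap(curves)
        for j in range(3):
            assert out.params[f"B1_{j}"].value == pytest.approx(0.0, abs=1e-3)
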