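"""Windowed correlator, ACF models, fitting and window scanning."""

import math

import numpy as np
import pytest

from chromodyn import polymer
from chromodyn.fcs import (
    CorrelationFunction,
    FocusModel,
    Trace,
    correlate,
    diffusion_acf,
    fit_diffusion,
    fit_relaxation,
    log_lag_grid,
    msd_from_fit,
    relaxation_acf,
    relaxation_component,
    upsilon_p,
    window_scan,
    windowed_expectation,
)
from chromodyn.fcs import _relaxation_bracket


def brute_force_windowed_cf(x, y, m, lag_idx):
    """Independent O(N^2)-style oracle: per non-overlapping window of m
    samples, plain nested-loop correlator with window-local means."""
    n_windows = len(x) // m
    out = []
    for w in range(n_windows):
        xs = x[w * m : (w + 1) * m]
        ys = y[w * m : (w + 1) * m]
        mx = sum(xs) / m
        my = sum(ys) / m
        if mx == 0 or my == 0:
            continue
        row = []
        for k in lag_idx:
            acc = 0.0
            for t in range(m - k):
                acc += (xs[t] - mx) * (ys[t + k] - my)
            row.append(acc / (m - k) / (mx * my))
        out.append(row)
    return np.mean(np.array(out), axis=0)


class TestCorrelate:
    def test_equals_brute_force_oracle(self, rng):
        """Windowed estimator equals the nested-loop oracle to 1e-10 for
        both ACF and CCF on a 1,000-sample two-channel trace."""
        n = 1000
        ch = np.stack([rng.poisson(3.0, n), rng.poisson(2.0, n)]).astype(float)
        trace = Trace(ch, dt=1e-3)
        m = 250
        for pair in [(0, 0), (1, 1), (0, 1)]:
            cf = correlate(trace, 0.25, pair=pair)
            lag_idx = np.round(cf.lags / trace.dt).astype(int)
            oracle = brute_force_windowed_cf(
                list(ch[pair[0]]), list(ch[pair[1]]), m, list(lag_idx)
            )
            assert np.allclose(cf.G, oracle, atol=1e-10)

    def test_constant_trace_zero(self):
        trace = Trace(np.full((1, 2000), 7.0), dt=1e-3)
        cf = correlate(trace, 0.5)
        assert np.allclose(cf.G, 0.0, atol=1e-12)

    def test_scaling_invariance(self, rng):
        x = rng.poisson(4.0, 4000).astype(float)
        cf1 = correlate(Trace(x, 1e-3), 0.5)
        cf2 = correlate(Trace(5.0 * x, 1e-3), 0.5)
        assert np.allclose(cf1.G, cf2.G, atol=1e-12)

    def test_independent_channels_uncorrelated(self, rng):
        n = 60000
        ch = np.stack([rng.poisson(5.0, n), rng.poisson(5.0, n)]).astype(float)
        cf = correlate(Trace(ch, 1e-4), 0.5, pair=(0, 1))
        assert np.all(np.abs(cf.G) < 3.5 * np.maximum(cf.se, 1e-12))

    def test_zero_mean_windows_skipped(self):
        x = np.concatenate([np.zeros(500), np.full(500, 3.0)])
        cf = correlate(Trace(x, 1e-3), 0.5)
        assert cf.n_skipped == 1 and cf.n_windows == 1

    def test_window_validation(self):
        trace = Trace(np.ones(100), 1e-3)
        with pytest.raises(ValueError):
            correlate(trace, 1.0)  # longer than trace
        with pytest.raises(ValueError):
            correlate(trace, 1e-3)  # shorter than 5 samples

    def test_log_lag_grid(self):
        lags = log_lag_grid(1e-4, 0.1)
        k = np.round(lags / 1e-4).astype(int)
        assert k[0] == 1 and k[-1] <= 1000
        assert np.all(np.diff(k) >= 1)


class TestDiffusionModel:
    def test_no_blinking_amplitude(self, focus):
        tau = np.array([0.0])
        g = diffusion_acf(tau, N=4.0, tau_D=1e-3, focus=focus, Theta_T=0.0)
        assert g[0] == pytest.approx(1.0 / 4.0, rel=1e-12)

    def test_noiseless_self_consistency(self, focus):
        tau = log_lag_grid(1e-5, 0.1)
        truth = dict(N=2.5, tau_D=8e-4, alpha=1.0)
        G = diffusion_acf(tau, truth["N"], truth["tau_D"], focus)
        cf = CorrelationFunction(tau, G, np.zeros_like(G), (0, 0), 1.0, 1)
        fit = fit_diffusion(cf, focus, fit_alpha=True)
        assert fit.N == pytest.approx(truth["N"], rel=1e-6)
        assert fit.tau_D == pytest.approx(truth["tau_D"], rel=1e-6)
        assert fit.alpha == pytest.approx(1.0, rel=1e-4)

    def test_d_from_tau_d(self, focus):
        # tau_D = w0^2/(4D): 200 nm, 0.5 ms -> 20 um^2/s
        tau = log_lag_grid(1e-5, 0.05)
        G = diffusion_acf(tau, 1.0, 5e-4, focus)
        cf = CorrelationFunction(tau, G, np.zeros_like(G), (0, 0), 1.0, 1)
        fit = fit_diffusion(cf, focus)
        assert fit.D == pytest.approx(20.0, rel=1e-4)


class TestRelaxationModel:
    def test_single_mode_limits(self, focus):
        """Each single-mode term: G(0) > 0, monotone non-increasing,
        G(inf) = 0."""
        tau = np.logspace(-5, 2, 400)
        for ups in (0.3, 2.0, 50.0):
            g = _relaxation_bracket(tau, 0.1, ups, focus.kappa)
            g0 = _relaxation_bracket(np.array([0.0]), 0.1, ups, focus.kappa)[0]
            assert g0 > 0
            assert np.all(np.diff(g) <= 1e-15)
            assert abs(g[-1]) < 1e-12

    def test_upsilon_closure(self, focus):
        # upsilon_p = 3 w0^2 / (4 a_p)
        assert upsilon_p(13408.0, focus) == pytest.approx(
            3 * 200.0**2 / (4 * 13408.0), rel=1e-12
        )

    def test_exact_form_linearizes_to_mode_covariance(self, focus, env):
        """For a_1 << w0^2 the compounded ACF reduces to the normalized
        segment-displacement autocovariance sum_p a_p e^(-tau/tau_p)."""
        sp = polymer.mode_spectrum(10.0, "theta_rosette", env)  # a_1 = 15 nm^2
        tau = np.logspace(-6, 0, 200)
        exact = relaxation_acf(tau, sp, focus, form="exact")
        cov = np.sum(
            sp.a_p[None, :] * np.exp(-tau[:, None] / sp.tau_p[None, :]), axis=1
        )
        assert np.allclose(exact / exact[0], cov / cov[0], atol=5e-3)

    def test_noiseless_composite_recovery(self, focus, env):
        """A noiseless composite curve at tau_1 = 161 ms / R_g = 297 nm is
        recovered exactly by the fit."""
        tau = log_lag_grid(2e-4, 1.0)
        shape = relaxation_component(tau, 0.161, "theta_rosette", focus, env)
        free = 0.1 * diffusion_acf(tau, 1.0, 1e-3, focus)
        G = 0.5 * shape + free
        cf = CorrelationFunction(tau, G, np.zeros_like(G), (0, 0), 100.0, 1, dt=2e-4)
        fit = fit_relaxation(cf, "theta_rosette", focus, env, bias_correction=False)
        assert fit.tau_1 == pytest.approx(0.161, rel=1e-4)
        assert fit.R_g == pytest.approx(297.0, rel=1e-3)
        assert fit.A_free == pytest.approx(0.1, rel=1e-2)

    def test_truncation_converged_at_default(self, focus, env):
        """With data carrying 64 modes, fitting at the default truncation
        (32 for theta) agrees with a 64-mode fit within 2 %: the default
        cut has converged."""
        tau = log_lag_grid(2e-4, 1.0)
        shape = relaxation_component(tau, 0.161, "theta_rosette", focus, env, p_max=64)
        cf = CorrelationFunction(tau, 0.5 * shape, np.zeros_like(shape), (0, 0), 100.0, 1, dt=2e-4)
        full = fit_relaxation(cf, "theta_rosette", focus, env, p_max=64,
                              include_free=False, bias_correction=False)
        default = fit_relaxation(cf, "theta_rosette", focus, env,
                                 include_free=False, bias_correction=False)
        assert default.p_max == 32
        assert abs(default.tau_1 - full.tau_1) / full.tau_1 < 0.02

    def test_windowed_expectation_constant_shift(self):
        """For a slowly decaying ACF the windowed-estimator expectation is
        the model minus roughly the window-mean variance."""
        g0, tau_c, window, dt = 0.1, 0.05, 5.0, 1e-3
        model = lambda t: g0 * np.exp(-np.asarray(t) / tau_c)
        lags = np.array([dt, 10 * dt, 100 * dt])
        E = windowed_expectation(model, window, dt, lags)
        W = 2 * g0 * tau_c / window  # leading-order mean variance
        assert np.allclose(model(lags) - E, W, rtol=0.1)


class TestMsdFromFit:
    def test_plateau_and_origin(self, focus, env):
        tau = log_lag_grid(2e-4, 1.0)
        shape = relaxation_component(tau, 0.161, "theta_rosette", focus, env)
        cf = CorrelationFunction(tau, shape, np.zeros_like(shape), (0, 0), 100.0, 1, dt=2e-4)
        fit = fit_relaxation(cf, "theta_rosette", focus, env,
                             include_free=False, bias_correction=False)
        curve = msd_from_fit(fit, np.linspace(0.0, 5.0, 50))
        assert curve.msd[0] == 0.0
        assert curve.plateau == pytest.approx(2 * fit.spectrum.a_p.sum(), rel=1e-12)


class TestWindowScan:
    def test_requires_spanning_grid(self):
        trace = Trace(np.ones(1000), 1e-3)
        with pytest.raises(ValueError):
            window_scan(trace, lambda cf: 1.0, [0.1, 0.2, 0.3])

    def test_plateau_selects_smallest_window(self, rng):
        trace = Trace(rng.poisson(5.0, 200000).astype(float), 1e-4)
        taus = {0.5: 0.1, 1.0: 0.102, 2.0: 0.098, 5.0: 0.2, 10.0: 0.4}

        def fake_fit(cf):
            return taus[round(cf.window, 3)]

        scan = window_scan(trace, fake_fit, list(taus))
        assert scan.valid and scan.selected_window == 0.5

    def test_monotone_no_plateau_invalid(self, rng):
        trace = Trace(rng.poisson(5.0, 200000).astype(float), 1e-4)
        scan = window_scan(trace, lambda cf: cf.window**2, [0.5, 1.0, 2.0, 5.0, 10.0])
        assert not scan.valid and scan.selected_window is None


class TestEndToEnd:
    def test_ou_trace_relaxation_recovery(self, focus, env):
        """Bound-emitter traces: the correlate -> fit chain recovers tau_1
        within 15 %.  A fast spectrum (R_g = 200 nm, tau_1 ~ 49 ms) keeps
        many relaxation times per trace at this scaled-down duration; the
        full euchromatin conditions run in the acceptance suite."""
        from chromodyn.synthetic import simulate_ou_trace
        from dataclasses import replace

        sp = polymer.mode_spectrum(200.0, "theta_rosette", env, p_max=16)
        truth_tau = sp.tau_1
        cfs = []
        for seed in range(4):
            trace, _ = simulate_ou_trace(
                sp, focus, n_emitters=100, dt=2e-4, duration=25.0, seed=seed
            )
            cfs.append(correlate(trace, 2.0))
        G = np.mean([c.G for c in cfs], axis=0)
        cf = replace(cfs[0], G=G, se=np.zeros_like(G))
        fit = fit_relaxation(cf, "theta_rosette", focus, env, p_max=16,
                             include_free=False)
        assert fit.tau_1 == pytest.approx(truth_tau, rel=0.15)

    def test_cross_correlation_of_comoving_labels(self, focus, env):
        """Co-moving two-channel emitters cross-correlate strongly;
        the CCF amplitude exceeds half the ACF geometric mean."""
        from chromodyn.synthetic import simulate_ou_trace

        sp = polymer.mode_spectrum(297.0, "theta_rosette", env)
        trace, _ = simulate_ou_trace(
            sp, focus, n_emitters=60, dt=2e-4, duration=20.0, seed=9, two_channel=True
        )
        cf11 = correlate(trace, 2.0, pair=(0, 0))
        cf22 = correlate(trace, 2.0, pair=(1, 1))
        cf12 = correlate(trace, 2.0, pair=(0, 1))
        band = slice(5, 25)  # lags above shot noise, below window effects
        g11 = cf11.G[band].mean()
        g22 = cf22.G[band].mean()
        g12 = cf12.G[band].mean()
        assert g12 > 0.5 * math.sqrt(g11 * g22)
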