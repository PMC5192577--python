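"""Closed-form polymer model: gyration radii, mode spectra, inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromodyn import polymer
from chromodyn.polymer import (
    ChromatinCalibration,
    Conformation,
    PhysicalEnvironment,
    PolymerParams,
    genomic_content,
    gyration_radius,
    mode_spectrum,
    parameter_surface,
    rg_from_relaxation,
    segment_msd,
)


class TestGyrationRadius:
    @pytest.mark.parametrize(
        "conf, L, lp, f, expected",
        [
            ("blob", 600.0, 2.0, 1, 20.0),  # R_g^2 = L lp / 3 = 400
            ("theta_rosette", 600.0, 2.0, 1, 14.142),  # half the blob variance
            ("theta_rosette", 12800.0, 100.0, 9, 211.598),
        ],
    )
    def test_examples(self, conf, L, lp, f, expected):
        rg = gyration_radius(PolymerParams(Conformation.parse(conf), L, lp, f))
        assert rg == pytest.approx(expected, rel=1e-4)

    def test_theta_rosette_vs_gaussian_loop_sampling(self):
        """Eq.-level check: R_g of sampled ideal Gaussian rosettes matches
        the closed form (Brownian-bridge loops sharing a base point)."""
        rng = np.random.default_rng(42)
        L, lp, f = 12800.0, 100.0, 9
        n, reps = 60, 800
        step_var = (2 * lp * (L / f) / n) / 3.0
        acc = 0.0
        for _ in range(reps):
            beads = [np.zeros((1, 3))]
            for _ in range(f):
                w = np.cumsum(rng.normal(0, math.sqrt(step_var), size=(n, 3)), axis=0)
                i = np.arange(1, n + 1)[:, None]
                beads.append((w - (i / n) * w[-1])[:-1])
            pts = np.vstack(beads)
            c = pts.mean(0)
            acc += ((pts - c) ** 2).sum(1).mean()
        rg_mc = math.sqrt(acc / reps)
        rg_eq = gyration_radius(PolymerParams(Conformation.parse("theta_rosette"), L, lp, f))
        assert rg_mc == pytest.approx(rg_eq, rel=0.03)

    def test_theta_f1_is_blob_over_sqrt2(self):
        for L, lp in [(500.0, 5.0), (30000.0, 150.0)]:
            blob = gyration_radius(PolymerParams(Conformation.parse("blob"), L, lp))
            theta = gyration_radius(
                PolymerParams(Conformation.parse("theta_rosette"), L, lp, 1)
            )
            assert theta == pytest.approx(blob / math.sqrt(2.0), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PolymerParams(Conformation.parse("blob"), -1.0, 2.0)
        with pytest.raises(ValueError):
            PolymerParams(Conformation.parse("blob"), 1.0, 0.0)
        with pytest.raises(ValueError):
            PolymerParams(Conformation.parse("theta_rosette"), 1.0, 1.0, 0)
        with pytest.raises(ValueError):
            Conformation.parse("fractal_fern")
        with pytest.raises(ValueError):
            Conformation.parse("globule_good")


class TestModeSpectrum:
    def test_theta_mode_time_ratio(self, env):
        sp = mode_spectrum(297.0, "theta_rosette", env, p_max=4)
        # tau_2 = tau_1 / 2^{3/2}
        assert sp.tau_p[1] == pytest.approx(sp.tau_1 / 2**1.5, rel=1e-12)
        assert sp.tau_1 * 1e3 == pytest.approx(161.0, rel=0.01)

    def test_theta_amplitude(self, env):
        sp = mode_spectrum(297.0, "theta_rosette", env)
        assert sp.a_1 == pytest.approx(0.152 * 297.0**2, rel=1e-12)
        assert sp.a_1 == pytest.approx(1.341e4, rel=1e-3)

    def test_globule_tau3(self, env):
        sp = mode_spectrum(100.0, "globule", env, p_max=5)
        scale = 0.191 / sp.tau_1
        assert sp.tau_p[2] * scale == pytest.approx(0.191 / 3.0, rel=1e-12)

    @pytest.mark.parametrize("conf", ["theta_rosette", "good_rosette", "globule", "blob"])
    def test_power_laws_and_monotonicity(self, conf, env):
        sp = mode_spectrum(250.0, conf, env, p_max=20)
        _, x_tau, _, x_a = polymer.mode_law_constants(conf)
        p = np.arange(1, 21)
        assert np.allclose(sp.tau_p / sp.tau_1, p ** (-x_tau), rtol=1e-12)
        assert np.allclose(sp.a_p / sp.a_1, p ** (-x_a), rtol=1e-12)
        assert np.all(np.diff(sp.tau_p) < 0) and np.all(np.diff(sp.a_p) < 0)

    def test_p_max_validation(self, env):
        with pytest.raises(ValueError):
            mode_spectrum(100.0, "blob", env, p_max=0)
        with pytest.raises(ValueError):
            mode_spectrum(-5.0, "blob", env)


class TestInversion:
    @pytest.mark.parametrize(
        "tau1_ms, conf, rg_expected",
        [
            (88.0, "theta_rosette", 243.0),
            (91.0, "theta_rosette", 245.6),
            (161.0, "theta_rosette", 297.0),
            (191.0, "good_rosette", 359.0),
            (191.0, "globule", 298.0),
        ],
    )
    def test_printed_pairs(self, tau1_ms, conf, rg_expected, env):
        """With eta calibrated once from (161 ms, 297 nm), the inversion
        reproduces the measured relaxation-time/size pairs within 1 %."""
        geom = rg_from_relaxation(tau1_ms * 1e-3, conf, env)
        assert geom.R_g == pytest.approx(rg_expected, rel=0.01)

    @pytest.mark.parametrize("conf", ["theta_rosette", "good_rosette", "globule", "blob"])
    @pytest.mark.parametrize("rg", [100.0, 243.0, 359.0])
    def test_roundtrip_identity(self, conf, rg, env):
        sp = mode_spectrum(rg, conf, env)
        geom = rg_from_relaxation(sp.tau_1, conf, env)
        assert geom.R_g == pytest.approx(rg, rel=1e-10)

    def test_rejects_nonpositive(self, env):
        with pytest.raises(ValueError):
            rg_from_relaxation(0.0, "blob", env)


class TestGenomicContent:
    def test_perinuclear_row(self):
        calib = ChromatinCalibration(rel_density=1.56)
        geom = polymer.DomainGeometry(
            R_g=245.0, V=0.724 * 4 / 3 * math.pi * 0.245**3
        )
        lo, hi = genomic_content(geom, calib)
        assert lo / 1e6 == pytest.approx(0.80, abs=0.01)
        assert hi / 1e6 == pytest.approx(1.12, abs=0.01)

    def test_euchromatin_row(self):
        calib = ChromatinCalibration(rel_density=0.91)
        geom = polymer.DomainGeometry(R_g=297.0, V=0.724 * 4 / 3 * math.pi * 0.297**3)
        lo, hi = genomic_content(geom, calib)
        assert lo / 1e6 == pytest.approx(0.83, abs=0.01)
        assert hi / 1e6 == pytest.approx(1.16, abs=0.01)

    def test_zero_concentration(self):
        calib = ChromatinCalibration(c_nuc=(0.0, 0.0), rel_density=1.0)
        geom = polymer.DomainGeometry(R_g=200.0, V=0.02)
        assert genomic_content(geom, calib) == (0.0, 0.0)


class TestSegmentMsd:
    def test_plateau_matches_zeta2_series(self, env):
        """Full theta series: plateau -> 2 * 0.152 * zeta(2) * R_g^2."""
        rg = 297.0
        sp = mode_spectrum(rg, "theta_rosette", env, p_max=4000)
        curve = segment_msd(sp, [10.0])
        analytic = 2 * 0.152 * (math.pi**2 / 6.0) * rg**2
        assert curve.plateau == pytest.approx(analytic, rel=1e-3)
        # truncated default spectrum stays within a few % of the full series
        sp_default = mode_spectrum(rg, "theta_rosette", env)
        assert segment_msd(sp_default, [10.0]).plateau == pytest.approx(analytic, rel=0.05)

    def test_zero_monotone_bounded(self, theta_spectrum_eu):
        t = np.linspace(0.0, 2.0, 300)
        curve = segment_msd(theta_spectrum_eu, t)
        assert curve.msd[0] == 0.0
        assert np.all(np.diff(curve.msd) > 0)
        assert np.all(curve.msd <= curve.plateau + 1e-9)


class TestParameterSurface:
    def test_blob_lp_closed_form_and_f_independence(self):
        calib = ChromatinCalibration()
        df = parameter_surface(297.0, 1.0e6, calib, "blob", density_grid=[4.5])
        assert len(df) == 1
        L = df.L_nm.iloc[0]
        assert df.l_p_nm.iloc[0] == pytest.approx(3 * 297.0**2 / L, rel=1e-12)

    def test_theta_lp_increases_with_f(self):
        calib = ChromatinCalibration()
        df = parameter_surface(297.0, 1.0e6, calib, "theta_rosette", density_grid=[4.5])
        lp = df.sort_values("f").l_p_nm.to_numpy()
        assert np.all(np.diff(lp) > 0)

    def test_quoted_combination(self):
        """gc = 1 Mb, 4.5 nuc/11 nm, f = 9, R_g = 297 nm -> l_p ~ 197 nm
        by closed-form inversion of the theta branch."""
        calib = ChromatinCalibration()
        df = parameter_surface(297.0, 1.0e6, calib, "theta_rosette", density_grid=[4.5])
        row = df[df.f == 9].iloc[0]
        assert row.l_p_nm == pytest.approx(197.0, rel=0.01)
        assert row.plausible  # inside the density/persistence/loop box


@settings(max_examples=40, deadline=None)
@given(
    L=st.floats(1e2, 1e6),
    lp=st.floats(1.0, 500.0),
    f=st.integers(1, 30),
    scale=st.floats(0.1, 10.0),
)
def test_rg_scale_covariance(L, lp, f, scale):
    """R_g(cL, c lp, f) = c R_g(L, lp, f) for the theta rosette and blob."""
    for conf in ("theta_rosette", "blob"):
        r1 = gyration_radius(PolymerParams(Conformation.parse(conf), L, lp, f))
        r2 = gyration_radius(
            PolymerParams(Conformation.parse(conf), scale * L, scale * lp, f)
        )
        assert r2 == pytest.approx(scale * r1, rel=1e-9)


@settings(max_examples=30, deadline=None)
@given(tau1=st.floats(1e-3, 1.0), f=st.integers(1, 20))
def test_spectrum_invariants(tau1, f):
    env = PhysicalEnvironment()
    geom = rg_from_relaxation(tau1, "theta_rosette", env)
    sp = mode_spectrum(geom.R_g, "theta_rosette", env)
    assert sp.tau_1 == pytest.approx(tau1, rel=1e-9)
    assert np.all(sp.a_p > 0) and np.all(sp.tau_p > 0)
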