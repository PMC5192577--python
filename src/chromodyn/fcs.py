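"""Fluorescence correlation spectroscopy of chromatin dynamics.

Intensity traces are correlated with a windowed (local-average)
estimator: the correlation function is computed over short tiles of
length Theta with tile-local means and averaged over the full trace,
which suppresses the contribution of processes slower than the window
(bulk photobleaching, cell movement).  Two model families are fitted:

* free (anomalous) diffusion through the confocal volume with optional
  fluorophore blinking — the classic FCS fit function; and
* polymer relaxation — a sum over the domain's Ornstein-Uhlenbeck
  relaxation modes observed through the Gaussian focus, whose
  characteristic times and amplitudes follow the conformation's mode
  laws, so a single fitted time constant (tau_1) pins the full spectrum
  and hence the domain's radius of gyration.

The window-size scan refits the model across a grid of window lengths
and requires a plateau of the fitted time constant, mirroring how
unstable traces are discarded in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from . import polymer
from .polymer import Conformation, ModeSpectrum, PhysicalEnvironment

__all__ = [
    "Trace",
    "CorrelationFunction",
    "FocusModel",
    "DiffusionFit",
    "RelaxationFit",
    "WindowScan",
    "log_lag_grid",
    "correlate",
    "diffusion_acf",
    "fit_diffusion",
    "relaxation_acf",
    "relaxation_component",
    "windowed_expectation",
    "fit_relaxation",
    "window_scan",
    "msd_from_fit",
]

MAX_LAG_FRACTION = 0.2  # lags are limited to Theta/5
POINTS_PER_OCTAVE = 8


@dataclass
class Trace:
    """Photon-count trace: one or two channels at fixed sampling interval."""

    channels: np.ndarray  # (n_channels, n_samples) counts per interval
    dt: float  # s

    def __post_init__(self) -> None:
        ch = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if ch.shape[0] > 2:
            raise ValueError("at most two channels")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(ch < 0):
            raise ValueError("counts must be non-negative")
        self.channels = ch

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt


@dataclass(frozen=True)
class CorrelationFunction:
    """Windowed correlation estimate G(tau) with per-lag standard errors."""

    lags: np.ndarray  # s, strictly increasing
    G: np.ndarray
    se: np.ndarray
    pair: tuple[int, int]  # channel indices (k, l); k == l: ACF
    window: float  # s
    n_windows: int
    n_skipped: int = 0
    dt: float = 0.0  # sampling interval; 0 means "use the smallest lag"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("non-finite correlation values")


@dataclass(frozen=True)
class FocusModel:
    """Confocal detection volume: 1/e^2 lateral and axial radii [nm]."""

    w_0: float = 200.0
    z_0: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.w_0 > 0 and self.z_0 > 0):
            raise ValueError("focal radii must be positive")
        if self.z_0 < self.w_0:
            raise ValueError("kappa = z_0/w_0 must be >= 1")

    @property
    def kappa(self) -> float:
        return self.z_0 / self.w_0


def log_lag_grid(dt: float, max_lag: float, points_per_octave: int = POINTS_PER_OCTAVE) -> np.ndarray:
    """Quasi-logarithmic lag grid [s]: integer multiples of dt, ~8/octave."""
    k_max = int(max_lag / dt)
    if k_max < 1:
        raise ValueError("max_lag below one sampling interval")
    n_oct = math.log2(k_max) if k_max > 1 else 0
    exps = np.arange(0, math.ceil((n_oct + 1) * points_per_octave) + 1)
    ks = np.unique(np.round(2.0 ** (exps / points_per_octave)).astype(int))
    ks = ks[(ks >= 1) & (ks <= k_max)]
    return ks * dt


def correlate(
    trace: Trace,
    window: float,
    lags: np.ndarray | None = None,
    pair: tuple[int, int] = (0, 0),
) -> CorrelationFunction:
    """Windowed auto-/cross-correlation.

    The trace is tiled into non-overlapping windows of length ``window``;
    in each, G(tau) = <dF_k(t) dF_l(t+tau)> / (<F_k><F_l>) with
    window-local means, then G is averaged over windows.  Windows with a
    vanishing mean are skipped and counted.  Lags are limited to a fifth
    of the window.
    """
    k, l = pair
    F_k = trace.channels[k]
    F_l = trace.channels[l]
    m = int(round(window / trace.dt))
    if m < 5:
        raise ValueError("window too short")
    if m > trace.n_samples:
        raise ValueError("window exceeds trace duration")
    if lags is None:
        lags = log_lag_grid(trace.dt, window * MAX_LAG_FRACTION)
    lags = np.asarray(lags, dtype=float)
    lag_idx = np.round(lags / trace.dt).astype(int)
    if np.any(lag_idx < 1) or np.any(lag_idx > m * MAX_LAG_FRACTION + 1e-9):
        raise ValueError("lags must lie in [dt, window/5]")
    n_windows = trace.n_samples // m
    per_window = np.full((n_windows, lag_idx.size), np.nan)
    skipped = 0
    for w in range(n_windows):
        x = F_k[w * m : (w + 1) * m]
        y = F_l[w * m : (w + 1) * m]
        mx, my = x.mean(), y.mean()
        if mx == 0.0 or my == 0.0:
            skipped += 1
            continue
        dx, dy = x - mx, y - my
        for j, ki in enumerate(lag_idx):
            per_window[w, j] = np.mean(dx[: m - ki] * dy[ki:]) / (mx * my)
    good = ~np.isnan(per_window[:, 0])
    if not good.any():
        raise ValueError("all windows skipped (zero mean)")
    vals = per_window[good]
    G = vals.mean(axis=0)
    se = (
        vals.std(axis=0, ddof=1) / math.sqrt(vals.shape[0])
        if vals.shape[0] > 1
        else np.zeros_like(G)
    )
    return CorrelationFunction(
        lags=lag_idx * trace.dt,
        G=G,
        se=se,
        pair=(k, l),
        window=m * trace.dt,
        n_windows=int(good.sum()),
        n_skipped=skipped,
        dt=trace.dt,
    )


# ----------------------------------------------------------------------------
# free-diffusion model


def diffusion_acf(
    tau: np.ndarray,
    N: float,
    tau_D: float,
    focus: FocusModel,
    alpha: float = 1.0,
    Theta_T: float = 0.0,
    tau_T: float = 1e-4,
) -> np.ndarray:
    """Free anomalous diffusion with fluorescent-protein-like blinking:

    G(tau) = (1/N) [1 - Theta_T + Theta_T e^{-tau/tau_T}]
             [1 + (tau/tau_D)^alpha]^{-1}
             [1 + (tau/tau_D)^alpha / kappa^2]^{-1/2}
    """
    tau = np.asarray(tau, dtype=float)
    x = (tau / tau_D) ** alpha
    blink = 1.0 - Theta_T + Theta_T * np.exp(-tau / tau_T)
    return (1.0 / N) * blink / ((1.0 + x) * np.sqrt(1.0 + x / focus.kappa**2))


@dataclass(frozen=True)
class DiffusionFit:
    """Fitted free-diffusion parameters; D in um^2/s via tau_D and w_0."""

    N: float
    tau_D: float  # s
    alpha: float
    Theta_T: float
    tau_T: float
    focus: FocusModel
    redchi: float
    result: object = field(repr=False, compare=False)

    @property
    def D(self) -> float:
        """Diffusion coefficient [um^2/s]: D = w_0^2 / (4 tau_D)."""
        return (self.focus.w_0 * 1e-3) ** 2 / (4.0 * self.tau_D)


def _weights(cf: CorrelationFunction) -> np.ndarray | None:
    if np.all(cf.se > 0):
        return 1.0 / cf.se
    return None


def fit_diffusion(
    cf: CorrelationFunction,
    focus: FocusModel,
    fit_blinking: bool = False,
    fit_alpha: bool = True,
    init: dict | None = None,
) -> DiffusionFit:
    """Weighted least-squares fit of the free-diffusion ACF model."""
    init = init or {}
    params = Parameters()
    G0 = max(float(cf.G[0]), 1e-8)
    params.add("N", value=init.get("N", 1.0 / G0), min=1e-6)
    params.add("tau_D", value=init.get("tau_D", cf.lags[len(cf.lags) // 2]), min=cf.lags[0] / 10)
    params.add("alpha", value=init.get("alpha", 1.0), min=0.1, max=2.0, vary=fit_alpha)
    params.add("Theta_T", value=init.get("Theta_T", 0.1 if fit_blinking else 0.0),
               min=0.0, max=0.99, vary=fit_blinking)
    params.add("tau_T", value=init.get("tau_T", 1e-4), min=1e-7, vary=fit_blinking)
    w = _weights(cf)

    def resid(p):
        model = diffusion_acf(
            cf.lags, p["N"], p["tau_D"], focus, p["alpha"], p["Theta_T"], p["tau_T"]
        )
        r = model - cf.G
        return r * w if w is not None else r

    out = minimize(resid, params)
    if not out.success:
        raise RuntimeError(f"diffusion fit failed: {out.message}")
    p = out.params
    return DiffusionFit(
        N=p["N"].value,
        tau_D=p["tau_D"].value,
        alpha=p["alpha"].value,
        Theta_T=p["Theta_T"].value,
        tau_T=p["tau_T"].value,
        focus=focus,
        redchi=out.redchi,
        result=out,
    )


# ----------------------------------------------------------------------------
# polymer-relaxation model


def _relaxation_bracket(
    tau: np.ndarray, tau_p: float, upsilon: float, kappa: float
) -> np.ndarray:
    """Single-mode relaxation correlator observed through a Gaussian focus.

    G_p(tau) ∝ [ (1 + (1 - e^{-tau/tau_p})/upsilon)^{-1}
                 (1 + (1 - e^{-tau/tau_p})/(kappa^2 upsilon))^{-1/2}
               - (1 + 1/upsilon)^{-1} (1 + 1/(kappa^2 upsilon))^{-1/2} ]

    with upsilon the ratio of the mode's diffusion correlation time to its
    relaxation time; the subtracted constant makes G vanish at infinity.
    """
    tau = np.asarray(tau, dtype=float)
    u = (1.0 - np.exp(-tau / tau_p)) / upsilon
    head = 1.0 / ((1.0 + u) * np.sqrt(1.0 + u / kappa**2))
    tail = 1.0 / ((1.0 + 1.0 / upsilon) * math.sqrt(1.0 + 1.0 / (kappa**2 * upsilon)))
    return head - tail


def upsilon_p(a_p: np.ndarray | float, focus: FocusModel) -> np.ndarray | float:
    """Mode ratio upsilon_p = 3 w_0^2 / (4 a_p).

    Follows from treating each mode as an Ornstein-Uhlenbeck process with
    per-axis variance a_p/3 and diffusivity D_p = a_p/(3 tau_p), so that
    tau_D,p / tau_p = 3 w_0^2/(4 a_p) with no free parameter.
    """
    return 3.0 * focus.w_0**2 / (4.0 * np.asarray(a_p, dtype=float))


def relaxation_acf(
    tau: np.ndarray,
    spectrum: ModeSpectrum,
    focus: FocusModel,
    form: str = "exact",
) -> np.ndarray:
    """Unnormalized multi-mode relaxation ACF.

    ``form="exact"``: the summation over modes is carried out inside the
    single-mode correlator — the compounded per-axis displacement variance
    sum_p (1 - e^{-tau/tau_p})/upsilon_p replaces the single-mode term, which
    is the exact ACF of a segment moving as the *sum* of its OU relaxation
    modes (collective motion) seen through the Gaussian focus.

    ``form="mode_sum"``: the literal sum over modes of a_p times the
    single-mode correlator.  Both forms agree to first order when all mode
    amplitudes are small against the focal radius (a_1 << w_0^2); at
    chromatin-domain amplitudes the exact composition must be used for the
    fitted time constant to be comparable with the generator's.
    """
    tau = np.asarray(tau, dtype=float)
    ups = np.atleast_1d(upsilon_p(spectrum.a_p, focus))
    if form == "mode_sum":
        out = np.zeros_like(tau)
        for a, tp, u in zip(spectrum.a_p, spectrum.tau_p, ups):
            out = out + a * _relaxation_bracket(tau, tp, u, focus.kappa)
        return out
    if form != "exact":
        raise ValueError("form must be 'exact' or 'mode_sum'")
    k2 = focus.kappa**2
    decay = 1.0 - np.exp(-tau[:, None] / spectrum.tau_p[None, :])
    u = (decay / ups[None, :]).sum(axis=1)
    u_inf = float((1.0 / ups).sum())
    head = 1.0 / ((1.0 + u) * np.sqrt(1.0 + u / k2))
    tail = 1.0 / ((1.0 + u_inf) * math.sqrt(1.0 + u_inf / k2))
    return spectrum.a_p.sum() * (head - tail)


def relaxation_component(
    tau: np.ndarray,
    tau_1: float,
    conformation: Conformation | str,
    focus: FocusModel,
    env: PhysicalEnvironment,
    p_max: int | None = None,
    form: str = "exact",
) -> np.ndarray:
    """Relaxation ACF shape, normalized to 1 at tau -> 0.

    tau_1 fixes the gyration radius through the conformation's relaxation
    law, hence the full mode spectrum; only the overall amplitude is left
    to the caller.
    """
    geom = polymer.rg_from_relaxation(tau_1, conformation, env)
    spectrum = polymer.mode_spectrum(geom.R_g, conformation, env, p_max)
    shape = relaxation_acf(tau, spectrum, focus, form)
    norm = relaxation_acf(np.array([0.0]), spectrum, focus, form)[0]
    return shape / norm


@dataclass(frozen=True)
class RelaxationFit:
    """Composite free-diffusion + polymer-relaxation fit."""

    tau_1: float  # s
    R_g: float  # nm
    amplitude: float  # relaxation amplitude (G scale)
    A_free: float  # free-diffusion amplitude
    tau_D_free: float  # s
    conformation: Conformation
    focus: FocusModel
    env: PhysicalEnvironment
    p_max: int
    redchi: float
    form: str = "exact"
    result: object = field(default=None, repr=False, compare=False)

    @property
    def spectrum(self) -> ModeSpectrum:
        return polymer.mode_spectrum(self.R_g, self.conformation, self.env, self.p_max)

    def model(self, tau: np.ndarray) -> np.ndarray:
        out = self.amplitude * relaxation_component(
            tau, self.tau_1, self.conformation, self.focus, self.env, self.p_max, self.form
        )
        if self.A_free > 0:
            out = out + self.A_free * diffusion_acf(
                tau, 1.0, self.tau_D_free, self.focus, alpha=1.0
            )
        return out


def windowed_expectation(
    model_curve, window: float, dt: float, lags: np.ndarray
) -> np.ndarray:
    """Exact expectation of the windowed correlator for a model ACF.

    Subtracting window-local means biases the estimator downward by the
    variance of the window mean and two mean-covariance cross terms.  For
    a window of m = window/dt samples and a model autocovariance g(k)
    (in G units), the expectation at integer lag k is

        E[G_hat(k)] = g(k) - 2 A(k) + V,
        A(k) = mean over allowed start times of the window-mean covariance,
        V    = variance of the window mean,

    all computable from cumulative sums of g.  Fits evaluate their model
    through this transform so the fitted parameters are free of
    window-size bias.
    """
    m = int(round(window / dt))
    lag_idx = np.round(np.asarray(lags) / dt).astype(int)
    t = np.arange(m) * dt
    g = np.asarray(model_curve(t), dtype=float)
    Gc = np.cumsum(g)
    idx = np.arange(m)
    phi = (Gc[idx] + Gc[m - 1 - idx] - g[0]) / m
    Phic = np.cumsum(phi)
    V = Phic[m - 1] / m
    A = Phic[m - 1 - lag_idx] / (m - lag_idx)
    return g[lag_idx] - 2.0 * A + V


def fit_relaxation(
    cf: CorrelationFunction,
    conformation: Conformation | str,
    focus: FocusModel,
    env: PhysicalEnvironment | None = None,
    p_max: int | None = None,
    include_free: bool = True,
    init: dict | None = None,
    form: str = "exact",
    bias_correction: bool = True,
) -> RelaxationFit:
    """Fit the composite chromatin ACF model.

    The composite is a fast free-diffusion term (alpha = 1) plus the
    polymer-relaxation sum whose shape is fully determined by tau_1 given
    the conformation and environment; amplitudes are free.  Weighted by
    the inverse per-lag standard error when available.  With
    ``bias_correction`` the expected offset of the windowed correlator is
    subtracted from the model (self-consistently, from the model curve at
    the current parameters), which removes the window-size dependence of
    the fitted relaxation time.
    """
    env = env or PhysicalEnvironment()
    conf = Conformation.parse(conformation)
    if p_max is None:
        p_max = polymer.default_p_max(conf)
    init = init or {}
    G0 = max(float(np.max(cf.G)), 1e-8)
    # crude time scale: lag where G first drops below half its initial value
    below = np.nonzero(cf.G < 0.5 * cf.G[0])[0]
    tau_half = cf.lags[below[0]] if below.size else cf.lags[-1] / 2
    params = Parameters()
    params.add("C", value=init.get("C", G0), min=0.0)
    params.add("tau_1", value=init.get("tau_1", tau_half), min=cf.lags[0], max=cf.lags[-1] * 100)
    params.add("A_free", value=init.get("A_free", 0.1 * G0 if include_free else 0.0),
               min=0.0, vary=include_free)
    params.add("tau_D_free", value=init.get("tau_D_free", 1e-3),
               min=cf.lags[0] / 10, max=5e-2, vary=include_free)
    w = _weights(cf)

    def model_at(p, tau):
        model = p["C"] * relaxation_component(tau, p["tau_1"], conf, focus, env, p_max, form)
        if include_free:
            model = model + p["A_free"] * diffusion_acf(
                tau, 1.0, p["tau_D_free"], focus, alpha=1.0
            )
        return model

    def resid(p):
        if bias_correction:
            model = windowed_expectation(
                lambda t: model_at(p, t), cf.window, cf.dt or cf.lags[0], cf.lags
            )
        else:
            model = model_at(p, cf.lags)
        r = model - cf.G
        return r * w if w is not None else r

    out = minimize(resid, params)
    if not out.success:
        raise RuntimeError(f"relaxation fit failed: {out.message}")
    p = out.params
    geom = polymer.rg_from_relaxation(p["tau_1"].value, conf, env)
    return RelaxationFit(
        tau_1=p["tau_1"].value,
        R_g=geom.R_g,
        amplitude=p["C"].value,
        A_free=p["A_free"].value if include_free else 0.0,
        tau_D_free=p["tau_D_free"].value if include_free else math.nan,
        conformation=conf,
        focus=focus,
        env=env,
        p_max=p_max,
        redchi=out.redchi,
        form=form,
        result=out,
    )


# ----------------------------------------------------------------------------
# window scan


@dataclass(frozen=True)
class WindowScan:
    """Stability of the fitted time constant across window sizes."""

    windows: np.ndarray  # s
    taus: np.ndarray  # fitted time constants (NaN where the fit failed)
    selected_window: float | None
    valid: bool

    def selected_index(self) -> int | None:
        if self.selected_window is None:
            return None
        return int(np.argmin(np.abs(self.windows - self.selected_window)))


def window_scan(
    trace: Trace,
    fit_func,
    windows: np.ndarray | list[float],
    pair: tuple[int, int] = (0, 0),
    rel_tol: float = 0.10,
) -> WindowScan:
    """Fit the time constant at every window size and find a plateau.

    ``fit_func(cf) -> tau`` runs the model fit on one correlation
    function.  The plateau is the longest run of consecutive window sizes
    whose fitted time constants change pairwise by less than ``rel_tol``;
    the smallest window of that run is selected.  Without any plateau of
    at least two windows the trace is flagged invalid.
    """
    windows = np.asarray(sorted(windows), dtype=float)
    if windows.size < 4 or windows[-1] / windows[0] < 10 * (1 - 1e-9):
        raise ValueError("need >= 4 window sizes spanning at least one decade")
    taus = np.full(windows.size, np.nan)
    for i, th in enumerate(windows):
        try:
            cf = correlate(trace, th, pair=pair)
            taus[i] = fit_func(cf)
        except Exception:
            continue
    best_run: tuple[int, int] | None = None  # (start, stop) inclusive
    run_start = None
    for i in range(windows.size - 1):
        ok = (
            np.isfinite(taus[i])
            and np.isfinite(taus[i + 1])
            and abs(taus[i + 1] - taus[i]) / abs(taus[i]) < rel_tol
        )
        if ok:
            if run_start is None:
                run_start = i
            if best_run is None or (i + 1 - run_start) > (best_run[1] - best_run[0]):
                best_run = (run_start, i + 1)
        else:
            run_start = None
    if best_run is None:
        return WindowScan(windows, taus, None, False)
    return WindowScan(windows, taus, float(windows[best_run[0]]), True)


def msd_from_fit(fit: RelaxationFit, times: np.ndarray) -> polymer.MsdCurve:
    """Segment MSD implied by a converged relaxation fit."""
    return polymer.segment_msd(fit.spectrum, times)
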