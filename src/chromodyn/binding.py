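"""Two-state chromatin-binding kinetics of linker histone H1.

H1 molecules associate with chromatin with rate ``k_on``, first into a
short-lived state from which they either dissociate again (``k_off1``) or
switch (``k_switch``) into a long-lived state that they leave with
``k_off2``.  The scheme is strictly sequential: free -> short -> long ->
free.  The module fits strip-FRAP profile series, integrated strip
recovery, continuous-photobleaching (CP) decays and point-FRAP bleach-time
series, and closes the scheme with steady-state rate algebra and residence
times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats
from scipy.special import erf

__all__ = [
    "BindingParams",
    "FrapProfileSeries",
    "CpCurve",
    "StripDiffusionFit",
    "fit_strip_profiles",
    "recovery_model",
    "fit_recovery",
    "cp_model",
    "fit_cp",
    "fit_point_frap",
    "steady_state_rates",
    "residence_times",
]


@dataclass(frozen=True)
class BindingParams:
    """Fractions and rates of the sequential two-state binding scheme."""

    f_free: float
    f_short: float
    f_long: float
    k_on: float = 0.0
    k_off1: float = 0.0
    k_switch: float = 0.0
    k_off2: float = 0.0

    def __post_init__(self) -> None:
        fr = (self.f_free, self.f_short, self.f_long)
        if any(f < 0 for f in fr):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")
        for name in ("k_on", "k_off1", "k_switch", "k_off2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FrapProfileSeries:
    """Strip-FRAP bleach profiles over time.

    ``profiles[i]`` is the normalized intensity vs ``positions`` [um] at
    ``times[i]`` [s]; ``h`` is the bleach-strip half-width [um].
    """

    times: np.ndarray
    positions: np.ndarray
    profiles: np.ndarray
    h: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        x = np.asarray(self.positions, float)
        p = np.atleast_2d(np.asarray(self.profiles, float))
        if p.shape != (t.size, x.size):
            raise ValueError("profiles must have shape (n_times, n_positions)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "profiles", p)


@dataclass(frozen=True)
class CpCurve:
    """Continuous-photobleaching decay, normalized to the initial intensity."""

    times: np.ndarray
    intensity: np.ndarray
    k_b: float  # bleach rate [1/s]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        y = np.asarray(self.intensity, float)
        if t.shape != y.shape:
            raise ValueError("times and intensity must match")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class StripDiffusionFit:
    """Result of the sigma^2(t) regression on a strip-FRAP profile series."""

    D_app: float  # um^2/s
    D_app_ci: tuple[float, float]  # 95 % CI on D_app
    sigma0: float  # um, width at t = 0
    sigma_t: np.ndarray  # fitted widths per time point
    slope_stderr: float


def _profile_width(positions: np.ndarray, profile: np.ndarray) -> float:
    """Width of a Gaussian depletion 1 - B exp(-x^2/(2 sigma^2))."""
    from scipy.optimize import curve_fit

    def model(x, B, sigma):
        return 1.0 - B * np.exp(-(x**2) / (2.0 * sigma**2))

    depth = max(1.0 - profile.min(), 1e-6)
    width0 = max(0.25 * (positions.max() - positions.min()), 1e-3)
    popt, _ = curve_fit(
        model,
        positions,
        profile,
        p0=(depth, width0),
        bounds=((0.0, 1e-6), (1.5, np.inf)),
        maxfev=10000,
    )
    return float(popt[1])


def fit_strip_profiles(series: FrapProfileSeries) -> StripDiffusionFit:
    """Apparent diffusion coefficient from bleach-profile broadening.

    Each post-bleach profile is fitted with a Gaussian depletion of width
    ``sigma``; the widths follow sigma^2(t) = sigma_0^2 + 2 D_app t for an
    effective (binding-coupled) diffusion process, so D_app is half the
    regression slope.  A negative slope is clipped to D_app = 0.
    """
    if series.times.size < 5:
        raise ValueError("need at least 5 time points for the regression")
    widths = np.array(
        [_profile_width(series.positions, p) for p in series.profiles]
    )
    res = stats.linregress(series.times, widths**2)
    dof = series.times.size - 2
    tcrit = stats.t.ppf(0.975, dof)
    D = res.slope / 2.0
    ci = (D - tcrit * res.stderr / 2.0, D + tcrit * res.stderr / 2.0)
    if D < 0:
        import warnings

        warnings.warn("negative broadening slope; reporting D_app = 0")
        D = 0.0
    return StripDiffusionFit(
        D_app=float(D),
        D_app_ci=(float(ci[0]), float(ci[1])),
        sigma0=float(math.sqrt(max(res.intercept, 0.0))),
        sigma_t=widths,
        slope_stderr=float(res.stderr),
    )


def recovery_model(
    t: np.ndarray,
    B: float,
    f_slow: float,
    f_mobile: float,
    D_app: float,
    k_off2: float,
    h: float,
    sigma0: float,
) -> np.ndarray:
    """Integrated strip-recovery curve with free, mobile and slow fractions.

    F(t) = 1 - B [ f_slow e^{-k_off2 t}
                   + f_mobile erf(h / sqrt(2 sigma_0^2 + 4 D_app t)) ]

    The freely diffusing fraction has already recovered at t = 0+, so it
    only lowers the bleach depth B relative to the total bound signal.
    """
    t = np.asarray(t, float)
    spread = np.sqrt(2.0 * sigma0**2 + 4.0 * D_app * t)
    return 1.0 - B * (f_slow * np.exp(-k_off2 * t) + f_mobile * erf(h / spread))


def fit_recovery(
    times: np.ndarray,
    curve: np.ndarray,
    h: float,
    sigma0: float,
    weights: np.ndarray | None = None,
):
    """Fit an integrated strip-recovery curve.

    The bleach is taken as complete inside the strip (B = 1), so the free
    fraction is identifiable from the instantaneous recovery at t = 0+:
    the bound pool ``f_bound`` splits into a slow share ``s`` (dissociation-
    limited, rate ``k_off2``) and a mobile share 1 - s (diffusion/binding-
    coupled, ``D_app``), with ``f_free = 1 - f_bound``.  Returns an lmfit
    result exposing derived ``f_free, f_slow, f_mobile`` plus ``D_app`` and
    ``k_off2``.
    """
    t = np.asarray(times, float)
    y = np.asarray(curve, float)

    def resid(p):
        m = recovery_model(
            t, 1.0, p["f_slow"], p["f_mobile"], p["D_app"], p["k_off2"], h, sigma0
        )
        r = m - y
        return r * weights if weights is not None else r

    best = None
    # the slow-exponential and slow-diffusion terms are partially degenerate;
    # a small multi-start avoids local minima
    for share0 in (0.2, 0.5, 0.8):
        for k0 in (1e-3, 1e-2, 1e-1):
            params = Parameters()
            params.add("f_bound", value=0.9, min=0.0, max=1.0)
            params.add("slow_share", value=share0, min=0.0, max=1.0)
            params.add("f_slow", expr="f_bound * slow_share")
            params.add("f_mobile", expr="f_bound * (1 - slow_share)")
            params.add("f_free", expr="1 - f_bound")
            params.add("D_app", value=0.01, min=1e-8)
            params.add("k_off2", value=k0, min=1e-8)
            try:
                out = minimize(resid, params)
            except Exception:
                continue
            if out.success and (best is None or out.chisqr < best.chisqr):
                best = out
    if best is None:
        raise RuntimeError("recovery fit did not converge from any start")
    return best


def cp_model(
    t: np.ndarray,
    f_free: float,
    f_1: float,
    f_2: float,
    k_off1: float,
    k_off2: float,
    k_b: float,
) -> np.ndarray:
    """Reaction-dominant continuous-photobleaching decay with two bound states.

    Bound molecules bleach with rate ``k_b`` while bound and are replaced by
    exchange with the unbleached pool at their dissociation rate, giving per
    state i the factor
    k_off,i/(k_off,i + k_b) + k_b/(k_off,i + k_b) exp(-(k_off,i + k_b) t);
    the free fraction is turned over too fast to bleach appreciably.
    """
    t = np.asarray(t, float)
    out = np.full_like(t, f_free, dtype=float)
    for f_i, k_off in ((f_1, k_off1), (f_2, k_off2)):
        ktot = k_off + k_b
        if ktot == 0:
            out = out + f_i
        else:
            out = out + f_i * (k_off / ktot + (k_b / ktot) * np.exp(-ktot * t))
    return out


def fit_cp(
    times: np.ndarray,
    intensity: np.ndarray,
    k_b: float,
    weights: np.ndarray | None = None,
):
    """Fit a normalized CP curve at known bleach rate ``k_b``.

    Returns an lmfit result with ``f_free, f_1, f_2, k_off1, k_off2``
    (fractions constrained to sum to 1, k_off1 > k_off2 by initialization).
    Rates far above ``k_b`` are only weakly identifiable; the caller should
    check the covariance.
    """
    t = np.asarray(times, float)
    y = np.asarray(intensity, float)

    def resid(p):
        m = cp_model(t, p["f_free"], p["f_1"], p["f_2"], p["k_off1"], p["k_off2"], k_b)
        r = m - y
        return r * weights if weights is not None else r

    best = None
    for k1_0 in (0.3, 1.0, 3.0):
        params = Parameters()
        params.add("f_free", value=0.1, min=0.0, max=1.0)
        params.add("f_1", value=0.2, min=0.0, max=1.0)
        params.add("f_2", expr="1 - f_free - f_1", min=0.0)
        params.add("k_off1", value=k1_0, min=1e-6)
        params.add("k_off2", value=0.01, min=1e-8)
        try:
            out = minimize(resid, params)
        except Exception:
            continue
        if out.success and (best is None or out.chisqr < best.chisqr):
            best = out
    if best is None:
        raise RuntimeError("CP fit did not converge from any start")
    return best


def fit_point_frap(curves: list[tuple[np.ndarray, np.ndarray]]):
    """Global two-exponential fit of point-FRAP recovery curves.

    ``curves`` is a list of (times, recovery) pairs acquired with different
    bleach durations.  The two dissociation rates are shared across all
    curves; the amplitudes (and the recovered plateau) are per curve:

    F_j(t) = A_j - B1_j exp(-k1 t) - B2_j exp(-k2 t)

    Requires at least 3 curves; returns an lmfit result with shared ``k1 >
    k2`` and per-curve amplitudes ``A_j, B1_j, B2_j``.
    """
    if len(curves) < 3:
        raise ValueError("global point-FRAP fit needs >= 3 bleach durations")
    params = Parameters()
    params.add("k1", value=1.0, min=1e-6)
    params.add("k2", value=0.01, min=1e-8)
    for j, (t, y) in enumerate(curves):
        span = float(np.ptp(y))
        params.add(f"A_{j}", value=float(np.max(y)), min=0.0)
        params.add(f"B1_{j}", value=0.5 * span if span > 0 else 0.0, min=0.0)
        params.add(f"B2_{j}", value=0.5 * span if span > 0 else 0.0, min=0.0)

    def resid(p):
        parts = []
        for j, (t, y) in enumerate(curves):
            m = (
                p[f"A_{j}"]
                - p[f"B1_{j}"] * np.exp(-p["k1"] * np.asarray(t, float))
                - p[f"B2_{j}"] * np.exp(-p["k2"] * np.asarray(t, float))
            )
            parts.append(m - np.asarray(y, float))
        return np.concatenate(parts)

    out = minimize(resid, params)
    if not out.success:
        raise RuntimeError(f"point-FRAP fit did not converge: {out.message}")
    return out


def steady_state_rates(
    f_free: float, f_short: float, f_long: float, k_off1: float, k_off2: float
) -> tuple[float, float]:
    """Close the sequential scheme from measured fractions and off-rates.

    At steady state of free -> short -> long -> free:

        k_switch = f_long k_off2 / f_short
        k_on     = f_short (k_off1 + k_switch) / f_free
    """
    if f_free <= 0 or f_short <= 0:
        raise ValueError("f_free and f_short must be positive")
    k_switch = f_long * k_off2 / f_short
    k_on = f_short * (k_off1 + k_switch) / f_free
    return k_on, k_switch


def residence_times(params: BindingParams) -> tuple[float, float, float]:
    """Residence times (t_short, t_long, t_mean) [s] of the bound states.

    t_short = 1/k_off1 and t_long = 1/k_off2 are the per-state lifetimes;
    the mean total bound time is the absorption time of the sequential
    scheme entered in the short-lived state:

        t_mean = 1/(k_off1 + k_switch)
                 + [k_switch/(k_off1 + k_switch)] / k_off2
    """
    if params.k_off1 <= 0 or params.k_off2 <= 0:
        raise ValueError("k_off1 and k_off2 must be positive")
    k1, ks, k2 = params.k_off1, params.k_switch, params.k_off2
    t_short = 1.0 / k1
    t_long = 1.0 / k2
    t_mean = 1.0 / (k1 + ks) + (ks / (k1 + ks)) * (1.0 / k2)
    return t_short, t_long, t_mean
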