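"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be emulated here: photon
count traces of freely diffusing and of chromatin-bound emitters (each
relaxation mode an exact-discretization Ornstein-Uhlenbeck process),
strip-FRAP profile/recovery series and continuous-photobleaching curves
from the two-binding-state scheme, and noisy contact maps with planted
loop bases.  All generators are deterministic given their seed and
return the ground truth alongside the data, so recovery tests compare
fitted parameters against the emitted truth rather than against
hard-coded numbers.

Noise model: photon shot noise is Poisson on binned counts; blinking is
a two-state telegraph process; bulk photobleaching is a multiplicative
exponential envelope.  Each ingredient can be switched off independently
to isolate failure modes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from . import binding as bind
from .binding import BindingParams, CpCurve, FrapProfileSeries
from .contact_map import ContactMap, contact_map_from_ensemble
from .domains import Dom, DomainConfig, Lin, Loop, parse_domain_config
from .fcs import FocusModel, Trace
from .lattice import LatticeSpec, sample_ensemble
from .polymer import ModeSpectrum

__all__ = [
    "simulate_ou_trace",
    "simulate_diffusion_trace",
    "mix_traces",
    "simulate_frap_profiles",
    "simulate_recovery",
    "simulate_cp",
    "simulate_point_frap",
    "planted_loop_bases",
    "simulate_contact_map",
    "focal_volume_integral",
]


def _detection(x: np.ndarray, y: np.ndarray, z: np.ndarray, focus: FocusModel) -> np.ndarray:
    return np.exp(-2.0 * (x**2 + y**2) / focus.w_0**2 - 2.0 * z**2 / focus.z_0**2)


def _telegraph(n: int, dt: float, theta_dark: float, tau_dark: float, rng) -> np.ndarray:
    """Two-state blinking process: 1 = bright, 0 = dark.

    Dark fraction theta_dark with dark-state lifetime tau_dark; bright
    lifetime follows from detailed balance.
    """
    tau_bright = tau_dark * (1.0 - theta_dark) / theta_dark
    p_db = 1.0 - math.exp(-dt / tau_dark)  # dark -> bright per step
    p_bd = 1.0 - math.exp(-dt / tau_bright)
    state = np.empty(n, dtype=np.float64)
    s = 0.0 if rng.random() < theta_dark else 1.0
    u = rng.random(n)
    for i in range(n):
        if s == 1.0 and u[i] < p_bd:
            s = 0.0
        elif s == 0.0 and u[i] < p_db:
            s = 1.0
        state[i] = s
    return state


def _ou_displacements(
    spectrum: ModeSpectrum, n: int, dt: float, rng, n_rows: int = 3
) -> np.ndarray:
    """Independent sums of the spectrum's OU modes, sampled exactly.

    The summed displacement is a stationary Gaussian process with
    autocovariance c(k) = sum_p (a_p/3) e^{-k dt/tau_p}, identical in law
    to summing exact-discretization OU processes mode by mode.  Rows are
    synthesized by circulant embedding (one FFT per pair of rows), which
    is exact for non-negative embedding spectra; tiny negative
    eigenvalues from finite truncation are clipped.  Returns an
    (n_rows, n) float32 array [nm] (three rows per emitter: x, y, z).
    """
    if n == 1:
        sd0 = math.sqrt(float(np.sum(spectrum.a_p)) / 3.0)
        return rng.normal(0.0, sd0, size=(n_rows, 1)).astype(np.float32)
    from scipy.fft import next_fast_len

    # circulant covariance on a ring of fast-FFT length >= 2n, using the
    # analytic continuation of c(k) (wrap distance on the ring)
    M = next_fast_len(2 * n, real=True)
    d = np.minimum(np.arange(M), M - np.arange(M))
    emb = np.zeros(M)
    for a_p, tau_p in zip(spectrum.a_p, spectrum.tau_p):
        emb += (a_p / 3.0) * np.exp(-d * dt / tau_p)
    lam = np.fft.fft(emb).real
    lam = np.clip(lam, 0.0, None)
    scale = np.sqrt(lam / M)
    disp = np.empty((n_rows, n), dtype=np.float32)
    n_pairs = (n_rows + 1) // 2
    batch = max(1, int(1.0e7 // M))  # ~300 MB complex working set
    pair = 0
    while pair < n_pairs:
        b = min(batch, n_pairs - pair)
        xi = rng.standard_normal((b, M)) + 1j * rng.standard_normal((b, M))
        xi *= scale
        y = np.fft.fft(xi, axis=1)
        for j in range(b):
            r = 2 * (pair + j)
            disp[r] = y[j].real[:n].astype(np.float32)
            if r + 1 < n_rows:
                disp[r + 1] = y[j].imag[:n].astype(np.float32)
        pair += b
    return disp


def simulate_ou_trace(
    spectrum: ModeSpectrum,
    focus: FocusModel,
    n_emitters: int = 250,
    brightness: float = 3.0e4,
    dt: float = 2.0e-4,
    duration: float = 60.0,
    seed: int = 0,
    box_halfwidth: tuple[float, float, float] | None = None,
    blinking: tuple[float, float] | None = None,
    bleach_tau: float | None = None,
    two_channel: bool = False,
) -> tuple[Trace, dict]:
    """Photon-count trace of chromatin-bound emitters.

    Each emitter is anchored uniformly in a box enclosing the focus and
    fluctuates about its anchor as the sum of the spectrum's OU modes.
    ``brightness`` is the peak count rate [Hz] of an emitter in the focus
    center.  With ``two_channel`` the same emitters are detected in two
    channels at half brightness each with independent shot noise
    (co-moving labels, as for two core histones in the same nucleosome).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    if dt > spectrum.tau_p[-1] / 5.0:
        warnings.warn(
            f"dt = {dt} s underresolves the fastest mode (tau = {spectrum.tau_p[-1]:.2e} s)"
        )
    if box_halfwidth is None:
        box_halfwidth = (2.0 * focus.w_0, 2.0 * focus.w_0, 1.5 * focus.z_0)
    rate = np.zeros(n)
    chunk = max(1, int(1.5e8 // max(n, 1) // 3))  # keep working set moderate
    done = 0
    inv_w2 = np.float32(2.0 / focus.w_0**2)
    inv_z2 = np.float32(2.0 / focus.z_0**2)
    while done < n_emitters:
        m = min(chunk, n_emitters - done)
        anchors = rng.uniform(-1.0, 1.0, size=(m, 3)) * np.asarray(box_halfwidth)
        disp = _ou_displacements(spectrum, n, dt, rng, n_rows=3 * m)
        x = disp[0::3] + anchors[:, 0:1].astype(np.float32)
        y = disp[1::3] + anchors[:, 1:2].astype(np.float32)
        z = disp[2::3] + anchors[:, 2:3].astype(np.float32)
        expo = (x * x + y * y) * inv_w2
        expo += (z * z) * inv_z2
        np.negative(expo, out=expo)
        np.exp(expo, out=expo)
        rate += expo.sum(axis=0, dtype=np.float64)
        done += m
    rate *= brightness
    if blinking is not None:
        theta_dark, tau_dark = blinking
        rate = rate * _telegraph(n, dt, theta_dark, tau_dark, rng)
    if bleach_tau is not None:
        rate = rate * np.exp(-np.arange(n) * dt / bleach_tau)
    if two_channel:
        counts = np.stack(
            [rng.poisson(0.5 * rate * dt), rng.poisson(0.5 * rate * dt)]
        ).astype(float)
    else:
        counts = rng.poisson(rate * dt)[None, :].astype(float)
    truth = {
        "scenario": "ou_bound",
        "tau_1": float(spectrum.tau_1),
        "R_g": float(spectrum.R_g),
        "conformation": spectrum.conformation.tag,
        "a_p": spectrum.a_p.tolist(),
        "tau_p": spectrum.tau_p.tolist(),
        "n_emitters": n_emitters,
        "brightness": brightness,
        "dt": dt,
        "duration": duration,
        "seed": seed,
        "blinking": blinking,
        "bleach_tau": bleach_tau,
    }
    return Trace(counts, dt), truth


def focal_volume_integral(focus: FocusModel) -> float:
    """Integral of the Gaussian detection profile over space [nm^3]."""
    return focus.w_0**2 * focus.z_0 * math.pi**1.5 / (2.0**1.5)


def simulate_diffusion_trace(
    D: float,
    focus: FocusModel,
    n_emitters: int = 40,
    brightness: float = 3.0e4,
    dt: float = 2.0e-5,
    duration: float = 20.0,
    seed: int = 0,
    box_halfwidth: tuple[float, float, float] | None = None,
) -> tuple[Trace, dict]:
    """Trace of emitters freely diffusing with coefficient ``D`` [um^2/s]
    in a periodic box around the focus."""
    if D <= 0:
        raise ValueError("D must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    if box_halfwidth is None:
        box_halfwidth = (3.0 * focus.w_0, 3.0 * focus.w_0, 1.5 * focus.z_0)
    box = np.asarray(box_halfwidth)
    D_nm2 = D * 1e6  # um^2/s -> nm^2/s
    step_sd = math.sqrt(2.0 * D_nm2 * dt)
    rate = np.zeros(n)
    for _ in range(n_emitters):
        start = rng.uniform(-box, box)
        steps = rng.standard_normal((n, 3)) * step_sd
        steps[0] = 0.0
        pos = start + np.cumsum(steps, axis=0)
        # wrap into the periodic box
        pos = (pos + box) % (2.0 * box) - box
        rate += _detection(pos[:, 0], pos[:, 1], pos[:, 2], focus)
    rate *= brightness
    counts = rng.poisson(rate * dt)[None, :].astype(float)
    tau_D = (focus.w_0 * 1e-3) ** 2 / (4.0 * D)
    mean_rate = (
        n_emitters * brightness * focal_volume_integral(focus) / np.prod(2.0 * box)
    )
    truth = {
        "scenario": "free_diffusion",
        "D": float(D),
        "tau_D": float(tau_D),
        "mean_counts_per_bin": float(mean_rate * dt),
        "n_emitters": n_emitters,
        "dt": dt,
        "duration": duration,
        "seed": seed,
    }
    return Trace(counts, dt), truth


def mix_traces(*traces: Trace) -> Trace:
    """Sum the counts of equally sampled traces (independent populations)."""
    dt = traces[0].dt
    n = min(t.n_samples for t in traces)
    if any(abs(t.dt - dt) > 1e-15 for t in traces):
        raise ValueError("traces must share the sampling interval")
    ch = sum(t.channels[:, :n] for t in traces)
    return Trace(ch, dt)


# ----------------------------------------------------------------------------
# FRAP / CP


def simulate_frap_profiles(
    D_app: float,
    sigma0: float,
    h: float,
    times: np.ndarray,
    positions: np.ndarray,
    depth: float = 0.8,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[FrapProfileSeries, dict]:
    """Strip-FRAP profile series with Gaussian depletion broadening.

    The depletion width follows sigma^2(t) = sigma0^2 + 2 D_app t; the
    depletion depth shrinks as sigma0/sigma(t) (conserved bleached
    population).  Gaussian noise of ``noise_sd`` is added per pixel.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    x = np.asarray(positions, float)
    sig2 = sigma0**2 + 2.0 * D_app * t
    profiles = np.empty((t.size, x.size))
    for i, s2 in enumerate(sig2):
        amp = depth * sigma0 / math.sqrt(s2)
        profiles[i] = 1.0 - amp * np.exp(-(x**2) / (2.0 * s2))
    profiles += rng.normal(0.0, noise_sd, size=profiles.shape)
    series = FrapProfileSeries(times=t, positions=x, profiles=profiles, h=h)
    truth = {
        "scenario": "frap_profiles",
        "D_app": float(D_app),
        "sigma0": float(sigma0),
        "depth": depth,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return series, truth


def simulate_recovery(
    params: BindingParams,
    D_app: float,
    h: float,
    sigma0: float,
    times: np.ndarray,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Integrated strip-recovery curve under the two-binding-state scheme.

    The slow (long-lived) bound fraction recovers by dissociation only;
    the short-lived fraction recovers by effective diffusion; the free
    fraction has recovered at t = 0+.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    curve = bind.recovery_model(
        t, 1.0, params.f_long, params.f_short, D_app, params.k_off2, h, sigma0
    )
    curve = curve + rng.normal(0.0, noise_sd, size=t.size)
    truth = {
        "scenario": "frap_recovery",
        "f_free": params.f_free,
        "f_slow": params.f_long,
        "f_mobile": params.f_short,
        "D_app": float(D_app),
        "k_off2": params.k_off2,
        "h": h,
        "sigma0": sigma0,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return curve, truth


def simulate_cp(
    params: BindingParams,
    k_b: float,
    times: np.ndarray,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[CpCurve, dict]:
    """Continuous-photobleaching decay for the two-binding-state scheme."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    y = bind.cp_model(
        t, params.f_free, params.f_short, params.f_long, params.k_off1, params.k_off2, k_b
    )
    y = y + rng.normal(0.0, noise_sd, size=t.size)
    curve = CpCurve(times=t, intensity=y, k_b=k_b)
    truth = {
        "scenario": "cp",
        "f_free": params.f_free,
        "f_1": params.f_short,
        "f_2": params.f_long,
        "k_off1": params.k_off1,
        "k_off2": params.k_off2,
        "k_b": k_b,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return curve, truth


def simulate_point_frap(
    k_off1: float,
    k_off2: float,
    bleach_durations: np.ndarray,
    times: np.ndarray,
    slow_share: float = 0.5,
    depth_rate: float = 2.0,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], dict]:
    """Point-FRAP recovery curves for a series of bleach durations.

    Longer bleaching deepens the bleach (depth 1 - e^{-depth_rate T_b});
    the recovery is two-exponential with the shared dissociation rates.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    curves = []
    for T_b in np.asarray(bleach_durations, float):
        depth = 1.0 - math.exp(-depth_rate * T_b)
        y = 1.0 - depth * (
            (1.0 - slow_share) * np.exp(-k_off1 * t) + slow_share * np.exp(-k_off2 * t)
        )
        y = y + rng.normal(0.0, noise_sd, size=t.size)
        curves.append((t.copy(), y))
    truth = {
        "scenario": "point_frap",
        "k_off1": k_off1,
        "k_off2": k_off2,
        "slow_share": slow_share,
        "bleach_durations": list(np.asarray(bleach_durations, float)),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return curves, truth


# ----------------------------------------------------------------------------
# contact maps


def planted_loop_bases(
    config: DomainConfig | str, lattice: LatticeSpec | None = None
) -> dict:
    """Ground-truth loop-base coordinates [bp] of a configuration.

    ``boundaries`` lists the genomic coordinates of the rosette centers'
    anchor points: the boundaries between consecutive loops plus the two
    outer ends of each domain's loop cluster (f + 1 coordinates for an
    f-loop domain).  ``pairs`` lists each loop's (start, end) coordinate
    pair — the two sites brought into contact by loop closure.
    """
    if isinstance(config, str):
        config = parse_domain_config(config, content_tolerance=None)
    lattice = lattice or LatticeSpec()
    boundaries: list[float] = []
    pairs: list[tuple[float, float]] = []
    bead = 0
    for element in config.elements:
        if isinstance(element, Lin):
            bead += lattice.beads(element.kb)
        elif isinstance(element, Dom) and element.is_rosette:
            for li, loop in enumerate(element.content):
                assert isinstance(loop, Loop)
                n = lattice.beads(loop.kb)
                start_bp = bead * lattice.bp_per_bond
                end_bp = (bead + n) * lattice.bp_per_bond
                boundaries.append(float(start_bp))
                pairs.append((float(start_bp), float(end_bp)))
                bead += n
            boundaries.append(float(bead * lattice.bp_per_bond))
        else:  # glob domain: no loop bases
            glob = element.content[0]
            bead += lattice.beads(glob.kb)
    return {"boundaries": boundaries, "pairs": pairs, "n_beads": bead}


def simulate_contact_map(
    config: DomainConfig | str,
    n_conformations: int = 100,
    reads_per_bin: int | None = None,
    seed: int = 0,
    lattice: LatticeSpec | None = None,
    **ensemble_kwargs,
) -> tuple[ContactMap, dict]:
    """Noisy contact map of a configuration with planted ground truth.

    The configuration is simulated with the lattice Monte Carlo, the
    ensemble converted to a contact map, and — when ``reads_per_bin`` is
    given — binomial sampling noise applied per matrix element,
    emulating finite sequencing depth.
    """
    if isinstance(config, str):
        config = parse_domain_config(config, content_tolerance=None)
    lattice = lattice or LatticeSpec()
    ens = sample_ensemble(config, n_conformations, seed=seed, lattice=lattice, **ensemble_kwargs)
    cmap = contact_map_from_ensemble(ens)
    if reads_per_bin is not None:
        rng = np.random.default_rng(seed + 1)
        m = cmap.matrix.copy()
        n = m.shape[0]
        iu = np.triu_indices(n)
        vals = m[iu]
        good = np.isfinite(vals)
        sampled = vals.copy()
        sampled[good] = rng.binomial(
            reads_per_bin, np.clip(vals[good], 0.0, 1.0)
        ) / float(reads_per_bin)
        m[iu] = sampled
        m.T[iu] = sampled
        cmap = ContactMap(m, bin_size=cmap.bin_size, start=cmap.start)
    truth = planted_loop_bases(config, lattice)
    truth.update(
        {
            "scenario": "contact_map",
            "n_conformations": n_conformations,
            "reads_per_bin": reads_per_bin,
            "seed": seed,
        }
    )
    return cmap, truth
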