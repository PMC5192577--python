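"""Closed-form polymer physics of independent chromatin domains.

A subchromosomal domain is modeled as a polymer of contour length ``L`` and
persistence length ``l_p`` that adopts one of four conformations: a
loop-rosette (cluster of ``f`` loops sharing a common base) under theta- or
good-solvent conditions, a compact (crumpled/fractal) globule, or a generic
blob.  Each conformation fixes the radius of gyration as a function of
``(L, l_p, f)`` and, through Zimm-type hydrodynamics, a discrete spectrum of
internal relaxation modes with times ``tau_p`` and amplitudes ``a_p`` that
are set by the domain's gyration radius, the solvent viscosity and the
temperature.  Inverting the first-mode relaxation time measured by FCS
therefore yields the domain's size, and — with a chromatin density
calibration — its genomic content.

Units: lengths in nm, times in s, genomic coordinates in bp, viscosity in
Pa*s, temperature in K.  Diffusion coefficients cross module boundaries in
um^2/s.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Topology",
    "Solvent",
    "Conformation",
    "PolymerParams",
    "PhysicalEnvironment",
    "ChromatinCalibration",
    "ModeSpectrum",
    "DomainGeometry",
    "MsdCurve",
    "gyration_radius",
    "mode_spectrum",
    "rg_from_relaxation",
    "genomic_content",
    "segment_msd",
    "parameter_surface",
    "default_p_max",
    "BOLTZMANN",
    "AVOGADRO",
]

BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: Default nuclear solvent viscosity [Pa*s], calibrated so that the
#: theta-solvent relaxation law maps tau_1 = 161 ms onto R_g = 297 nm at
#: T = 310.15 K (euchromatin reference pair).
DEFAULT_ETA_S = 4.306e-3
DEFAULT_T = 310.15


class Topology(str, enum.Enum):
    LOOP_ROSETTE = "loop_rosette"
    GLOBULE = "globule"
    BLOB = "blob"


class Solvent(str, enum.Enum):
    THETA = "theta"
    GOOD = "good"


@dataclass(frozen=True)
class Conformation:
    """A (topology, solvent) tag selecting one branch of the model.

    ``solvent`` is meaningful only for the loop rosette; the globule and the
    blob accept but ignore it.
    """

    topology: Topology
    solvent: Solvent = Solvent.THETA

    def __post_init__(self) -> None:
        topo = Topology(self.topology)
        solv = Solvent(self.solvent)
        object.__setattr__(self, "topology", topo)
        object.__setattr__(self, "solvent", solv)
        if topo is not Topology.LOOP_ROSETTE and solv is Solvent.GOOD:
            # good-solvent swelling is only parameterized for rosettes
            raise ValueError(
                f"solvent={solv.value!r} is only defined for the loop rosette"
            )

    @classmethod
    def parse(cls, value: "Conformation | str") -> "Conformation":
        """Parse tags like ``'theta_rosette'``, ``'globule'``, ``'blob'``."""
        if isinstance(value, Conformation):
            return value
        key = str(value).strip().lower().replace("-", "_").replace(" ", "_")
        aliases = {
            "theta_rosette": (Topology.LOOP_ROSETTE, Solvent.THETA),
            "rosette_theta": (Topology.LOOP_ROSETTE, Solvent.THETA),
            "loop_rosette": (Topology.LOOP_ROSETTE, Solvent.THETA),
            "good_rosette": (Topology.LOOP_ROSETTE, Solvent.GOOD),
            "rosette_good": (Topology.LOOP_ROSETTE, Solvent.GOOD),
            "loop_rosette_good": (Topology.LOOP_ROSETTE, Solvent.GOOD),
            "globule": (Topology.GLOBULE, Solvent.THETA),
            "blob": (Topology.BLOB, Solvent.THETA),
        }
        if key not in aliases:
            raise ValueError(f"unknown conformation tag {value!r}")
        topo, solv = aliases[key]
        return cls(topo, solv)

    @property
    def tag(self) -> str:
        if self.topology is Topology.LOOP_ROSETTE:
            return f"{self.solvent.value}_rosette"
        return self.topology.value


# Relaxation-law constants per conformation: tau_1 = c_tau * eta_s R_g^3 / kBT,
# tau_p = tau_1 / p^x_tau, a_p = c_a * R_g^2 / p^x_a.
_MODE_LAWS: dict[tuple[Topology, Solvent], tuple[float, float, float, float]] = {
    (Topology.LOOP_ROSETTE, Solvent.THETA): (6.111, 1.5, 0.152, 2.0),
    (Topology.LOOP_ROSETTE, Solvent.GOOD): (4.114, 17.0 / 20.0, 0.172, 9.0 / 4.0),
    (Topology.GLOBULE, Solvent.THETA): (7.151, 1.0, 0.236, 5.0 / 3.0),
    (Topology.BLOB, Solvent.THETA): (5.849, 1.5, 0.152, 2.0),
}


def mode_law_constants(conformation: Conformation | str) -> tuple[float, float, float, float]:
    """Return ``(c_tau, x_tau, c_a, x_a)`` for a conformation tag."""
    conf = Conformation.parse(conformation)
    return _MODE_LAWS[(conf.topology, conf.solvent)]


@dataclass(frozen=True)
class PolymerParams:
    """Static description of a domain: conformation plus ``(L, l_p, f)``.

    L : contour length of the chromatin fiber in the domain [nm]
    l_p : persistence length [nm]
    f : number of loops (>= 1); ignored by globule and blob
    """

    conformation: Conformation
    L: float
    l_p: float
    f: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "conformation", Conformation.parse(self.conformation))
        if not self.L > 0:
            raise ValueError(f"contour length L must be positive, got {self.L}")
        if not self.l_p > 0:
            raise ValueError(f"persistence length l_p must be positive, got {self.l_p}")
        if int(self.f) != self.f or self.f < 1:
            raise ValueError(f"loop count f must be an integer >= 1, got {self.f}")
        object.__setattr__(self, "f", int(self.f))


@dataclass(frozen=True)
class PhysicalEnvironment:
    """Solvent viscosity and temperature of the nucleoplasm."""

    eta_s: float = DEFAULT_ETA_S
    T: float = DEFAULT_T

    def __post_init__(self) -> None:
        if not self.eta_s > 0:
            raise ValueError("eta_s must be positive")
        if not self.T > 0:
            raise ValueError("T must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy [J]."""
        return BOLTZMANN * self.T


@dataclass(frozen=True)
class ChromatinCalibration:
    """Calibration constants linking domain volume to genomic content.

    NRL : nucleosomal repeat length [bp per nucleosome]
    c_nuc : (low, high) mean nuclear nucleosome concentration [uM]
    rel_density : local nucleosome density relative to the nuclear mean
        (0.91 for euchromatin, 1.56 for heterochromatin)
    chi_V : dimensionless prefactor of the effective domain volume
        V = chi_V * (4/3) pi R_g^3; calibrated so the heterochromatin and
        euchromatin (R_g, genomic-content) pairs are mutually consistent.
    """

    NRL: float = 191.0
    c_nuc: tuple[float, float] = (100.0, 140.0)
    rel_density: float = 1.0
    chi_V: float = 0.724

    def __post_init__(self) -> None:
        lo, hi = self.c_nuc
        if not (self.NRL > 0 and lo > 0 or lo == 0) or hi < lo:
            raise ValueError("invalid calibration: need NRL > 0 and 0 <= c_lo <= c_hi")
        if lo < 0 or self.NRL <= 0 or self.rel_density < 0 or self.chi_V <= 0:
            raise ValueError("calibration constants must be non-negative (NRL, chi_V positive)")


@dataclass(frozen=True)
class ModeSpectrum:
    """Discrete relaxation-mode spectrum of a domain.

    tau_p[i] is the relaxation time [s] and a_p[i] the mean-squared mode
    amplitude [nm^2] of mode p = i + 1.  Both decrease strictly with p
    following the power law of the tagged conformation.
    """

    conformation: Conformation
    tau_p: np.ndarray
    a_p: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_p, dtype=float)
        amp = np.asarray(self.a_p, dtype=float)
        object.__setattr__(self, "tau_p", tau)
        object.__setattr__(self, "a_p", amp)
        object.__setattr__(self, "conformation", Conformation.parse(self.conformation))
        if tau.shape != amp.shape or tau.ndim != 1 or tau.size < 1:
            raise ValueError("tau_p and a_p must be 1-d arrays of equal length >= 1")
        if np.any(tau <= 0) or np.any(amp <= 0):
            raise ValueError("mode times and amplitudes must be positive")
        if np.any(np.diff(tau) >= 0) or np.any(np.diff(amp) >= 0):
            raise ValueError("tau_p and a_p must decrease strictly with p")

    @property
    def p_max(self) -> int:
        return int(self.tau_p.size)

    @property
    def tau_1(self) -> float:
        return float(self.tau_p[0])

    @property
    def a_1(self) -> float:
        return float(self.a_p[0])

    @property
    def R_g(self) -> float:
        """Gyration radius [nm] implied by a_1 via the conformation's law."""
        _, _, c_a, _ = mode_law_constants(self.conformation)
        return math.sqrt(self.a_1 / c_a)


@dataclass(frozen=True)
class DomainGeometry:
    """Domain size: gyration radius, effective volume, genomic content."""

    R_g: float
    V: float  # um^3
    gc_range: tuple[float, float] | None = None  # bp

    def __post_init__(self) -> None:
        if not (self.R_g > 0 and self.V > 0):
            raise ValueError("R_g and V must be positive")
        if self.gc_range is not None and self.gc_range[0] > self.gc_range[1]:
            raise ValueError("gc_range lower bound exceeds upper bound")


@dataclass(frozen=True)
class MsdCurve:
    """Mean-squared displacement of a chain segment about the domain centroid."""

    times: np.ndarray  # s
    msd: np.ndarray  # nm^2
    plateau: float  # nm^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "msd", np.asarray(self.msd, dtype=float))


def gyration_radius(params: PolymerParams) -> float:
    """Radius of gyration [nm] of a domain in the given conformation.

    The four branches are

    ====================  =======================================================
    theta rosette         R_g^2 = (L l_p / 6) (2f - 1)/f^2
    good-solvent rosette  R_g^2 = (L^{6/5} l_p^{4/5} / 9.59) (1.92 f - 0.92)/f^{11/5}
    globule               R_g^2 = L^{2/3} l_p^{4/3} / 1.76
    blob                  R_g^2 = L l_p / 3
    ====================  =======================================================
    """
    conf = params.conformation
    L, lp, f = params.L, params.l_p, params.f
    if conf.topology is Topology.LOOP_ROSETTE and conf.solvent is Solvent.THETA:
        rg2 = (L * lp / 6.0) * (2.0 * f - 1.0) / f**2
    elif conf.topology is Topology.LOOP_ROSETTE and conf.solvent is Solvent.GOOD:
        rg2 = (L ** (6.0 / 5.0) * lp ** (4.0 / 5.0) / 9.59) * (1.92 * f - 0.92) / f ** (11.0 / 5.0)
    elif conf.topology is Topology.GLOBULE:
        rg2 = L ** (2.0 / 3.0) * lp ** (4.0 / 3.0) / 1.76
    elif conf.topology is Topology.BLOB:
        rg2 = L * lp / 3.0
    else:  # pragma: no cover - enum exhausted above
        raise ValueError(f"unknown conformation {conf}")
    return math.sqrt(rg2)


def default_p_max(conformation: Conformation | str, cutoff: float = 1e-3, cap: int = 50) -> int:
    """Smallest truncation order with a_p/a_1 < ``cutoff``, capped at ``cap``."""
    _, _, _, x_a = mode_law_constants(conformation)
    p = math.ceil(cutoff ** (-1.0 / x_a))
    return int(min(max(p, 1), cap))


def mode_spectrum(
    R_g: float,
    conformation: Conformation | str,
    env: PhysicalEnvironment | None = None,
    p_max: int | None = None,
) -> ModeSpectrum:
    """Relaxation-mode spectrum of a domain with gyration radius ``R_g`` [nm].

    tau_1 = c_tau * eta_s R_g^3 / kBT with the conformation's prefactor, the
    higher modes following tau_p = tau_1/p^{x_tau} and a_p = c_a R_g^2/p^{x_a}.
    """
    if not R_g > 0:
        raise ValueError("R_g must be positive")
    env = env or PhysicalEnvironment()
    conf = Conformation.parse(conformation)
    if p_max is None:
        p_max = default_p_max(conf)
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    c_tau, x_tau, c_a, x_a = mode_law_constants(conf)
    rg_m = R_g * 1e-9
    tau_1 = c_tau * env.eta_s * rg_m**3 / env.kBT
    p = np.arange(1, p_max + 1, dtype=float)
    return ModeSpectrum(conf, tau_1 / p**x_tau, c_a * R_g**2 / p**x_a)


def rg_from_relaxation(
    tau_1: float,
    conformation: Conformation | str,
    env: PhysicalEnvironment | None = None,
    calib: ChromatinCalibration | None = None,
) -> DomainGeometry:
    """Invert the first-mode relaxation time [s] to a domain geometry.

    R_g = (tau_1 kBT / (c_tau eta_s))^{1/3}; the effective volume uses the
    calibrated convention V = chi_V (4/3) pi R_g^3.  If a calibration with a
    local density is supplied, the genomic-content interval is attached.
    """
    if not tau_1 > 0:
        raise ValueError("tau_1 must be positive")
    env = env or PhysicalEnvironment()
    c_tau, _, _, _ = mode_law_constants(conformation)
    rg_m = (tau_1 * env.kBT / (c_tau * env.eta_s)) ** (1.0 / 3.0)
    R_g = rg_m * 1e9
    calib = calib or ChromatinCalibration()
    V_um3 = calib.chi_V * (4.0 / 3.0) * math.pi * (R_g * 1e-3) ** 3
    geom = DomainGeometry(R_g=R_g, V=V_um3)
    gc = genomic_content(geom, calib)
    return DomainGeometry(R_g=R_g, V=V_um3, gc_range=gc)


def genomic_content(
    geom: DomainGeometry, calib: ChromatinCalibration
) -> tuple[float, float]:
    """Genomic content interval [bp] of a domain of effective volume ``geom.V``.

    The number of nucleosomes in the domain is the local nucleosome
    concentration (relative density x mean concentration) times the effective
    volume; times the repeat length this gives base pairs.  Evaluated at both
    endpoints of the mean-concentration interval.
    """
    V_liters = geom.V * 1e-15  # um^3 -> L
    out = []
    for c_uM in calib.c_nuc:
        n_nuc = calib.rel_density * (c_uM * 1e-6) * AVOGADRO * V_liters
        out.append(n_nuc * calib.NRL)
    lo, hi = sorted(out)
    return (lo, hi)


def segment_msd(spectrum: ModeSpectrum, times: Sequence[float] | np.ndarray) -> MsdCurve:
    """MSD of a chain segment from the mode spectrum.

    msd(t) = 2 sum_p a_p (1 - exp(-t/tau_p)); the plateau 2 sum_p a_p is the
    stationary variance of the equivalent Ornstein-Uhlenbeck mode ensemble,
    i.e. the confinement volume of the segment about the domain centroid.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    msd = 2.0 * np.sum(
        spectrum.a_p[None, :] * (1.0 - np.exp(-t[:, None] / spectrum.tau_p[None, :])),
        axis=1,
    )
    plateau = 2.0 * float(np.sum(spectrum.a_p))
    return MsdCurve(times=t, msd=msd, plateau=plateau)


def _solve_lp(conf: Conformation, R_g: float, L: float, f: int) -> float:
    """Invert the gyration-radius branch for the persistence length."""
    rg2 = R_g * R_g
    if conf.topology is Topology.LOOP_ROSETTE and conf.solvent is Solvent.THETA:
        return 6.0 * rg2 * f**2 / (L * (2.0 * f - 1.0))
    if conf.topology is Topology.LOOP_ROSETTE and conf.solvent is Solvent.GOOD:
        base = 9.59 * rg2 * f ** (11.0 / 5.0) / (L ** (6.0 / 5.0) * (1.92 * f - 0.92))
        return base ** (5.0 / 4.0)
    if conf.topology is Topology.GLOBULE:
        return (1.76 * rg2 / L ** (2.0 / 3.0)) ** (3.0 / 4.0)
    return 3.0 * rg2 / L  # blob


def parameter_surface(
    R_g: float,
    gc: float,
    calib: ChromatinCalibration,
    conformation: Conformation | str,
    f_grid: Sequence[int] = tuple(range(1, 21)),
    density_grid: Sequence[float] | None = None,
    plausibility: tuple[tuple[float, float], tuple[float, float], int] = (
        (0.5, 6.0),
        (10.0, 200.0),
        20,
    ),
):
    """Persistence length vs (mass density, loop count) at fixed (R_g, gc).

    For each candidate linear mass density [nucleosomes per 11 nm] and loop
    count, the fiber contour length in the domain is
    ``L = gc / (density * NRL / 11 nm)`` and the persistence length solves the
    gyration-radius branch.  Rows inside the plausibility box
    (density 0.5-6 nuc/11 nm, l_p 10-200 nm, f <= 20) are flagged.

    Returns a pandas DataFrame with columns
    ``density_nuc_per_11nm, f, L_nm, l_p_nm, plausible``.
    """
    import pandas as pd

    if not (R_g > 0 and gc > 0):
        raise ValueError("R_g and gc must be positive")
    conf = Conformation.parse(conformation)
    if density_grid is None:
        density_grid = np.arange(0.5, 6.01, 0.25)
    (d_lo, d_hi), (lp_lo, lp_hi), f_cap = plausibility
    f_values = list(f_grid) if conf.topology is Topology.LOOP_ROSETTE else [1]
    rows = []
    for density in density_grid:
        bp_per_nm = density * calib.NRL / 11.0
        L = gc / bp_per_nm
        for f in f_values:
            lp = _solve_lp(conf, R_g, L, int(f))
            if not (np.isfinite(lp) and lp > 0):
                continue
            plausible = (d_lo <= density <= d_hi) and (lp_lo <= lp <= lp_hi) and f <= f_cap
            rows.append(
                {
                    "density_nuc_per_11nm": float(density),
                    "f": int(f),
                    "L_nm": float(L),
                    "l_p_nm": float(lp),
                    "plausible": bool(plausible),
                }
            )
    return pd.DataFrame(rows)
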