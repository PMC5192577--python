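"""Loop-base detection in genomic contact-probability maps.

The pipeline mirrors classic 3C-map peak analysis of hand-selected
domains: the diagonal and its vicinity are masked, a one-dimensional
global profile (average of a maximum and a mean projection) is computed,
peaks are located by sliding parabolic fits and thresholded against the
profile average, and for every peak an orthogonal local projection
reveals the partner sites with which it forms loops.  Pairs recovered
from both anchors are high-confidence loop bases; one-directional pairs
are low confidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .contact_map import ContactMap

__all__ = [
    "Profile",
    "LoopCall",
    "extract_domain",
    "global_profile",
    "detect_peaks",
    "local_projection",
    "call_loop_bases",
]

DEFAULT_FIT_WINDOW = 30_000.0  # bp, 12 points at 2.5 kb
DEFAULT_THRESHOLD_FRAC = 0.8
DEFAULT_DIAG_MASK = 30_000.0  # bp, low end of the +-30-75 kb range
DEFAULT_LOCAL_HALFWIDTH = 27_500.0  # bp, middle of the 25-30 kb vicinity


@dataclass(frozen=True)
class Profile:
    """1-D projection of a domain map; NaN marks all-masked columns."""

    positions: np.ndarray  # bp, strictly increasing (bin midpoints)
    values: np.ndarray
    kind: str = "global"  # "global" or "local"
    anchor: float | None = None  # bp, for local projections

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, float)
        v = np.asarray(self.values, float)
        if p.shape != v.shape or p.ndim != 1:
            raise ValueError("positions and values must be matching 1-d arrays")
        if np.any(np.diff(p) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class LoopCall:
    """A detected loop base: two genomic sites in contact."""

    site_i: float  # bp
    site_j: float  # bp
    confidence: str  # "high" (both directions) or "low"

    def __post_init__(self) -> None:
        if not self.site_i < self.site_j:
            raise ValueError("site_i must be < site_j")
        if self.confidence not in ("high", "low"):
            raise ValueError("confidence must be 'high' or 'low'")


def extract_domain(
    cmap: ContactMap,
    interval: tuple[float, float],
    diag_mask_halfwidth: float = DEFAULT_DIAG_MASK,
) -> ContactMap:
    """Cut a domain submatrix and mask the diagonal band as missing.

    ``interval`` is a genomic (start, end) in bp; the diagonal and its
    vicinity of ``+-diag_mask_halfwidth`` bp are set to NaN (a halfwidth of
    0 removes only the diagonal itself).
    """
    lo, hi = interval
    if lo >= hi:
        raise ValueError("empty interval")
    i0 = cmap.bin_of(lo)
    i1 = cmap.bin_of(hi - 1) + 1
    if i0 < 0 or i1 > cmap.n_bins:
        raise ValueError(
            f"interval {interval} outside map [{cmap.start}, "
            f"{cmap.start + cmap.n_bins * cmap.bin_size})"
        )
    sub = cmap.matrix[i0:i1, i0:i1].copy()
    n = sub.shape[0]
    k = int(diag_mask_halfwidth // cmap.bin_size)
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= k
    sub[band] = np.nan
    return ContactMap(sub, bin_size=cmap.bin_size, start=cmap.start + i0 * cmap.bin_size)


def _positions(cmap: ContactMap) -> np.ndarray:
    return cmap.start + (np.arange(cmap.n_bins) + 0.5) * cmap.bin_size


def global_profile(domain_map: ContactMap) -> Profile:
    """Per-column average of the maximum and the mean projection."""
    m = domain_map.matrix
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_max = np.nanmax(np.where(np.isnan(m), -np.inf, m), axis=0)
        col_mean = np.nanmean(m, axis=0)
    all_missing = np.all(np.isnan(m), axis=0)
    values = (col_max + col_mean) / 2.0
    values[all_missing] = np.nan
    return Profile(_positions(domain_map), values, kind="global")


def _roughness(values: np.ndarray) -> float:
    """Robust point-to-point noise scale of a profile.

    Second differences cancel smooth trends; for white noise of variance
    s^2 they have variance 6 s^2, so s = 1.4826 MAD(d2) / sqrt(6).
    """
    d2 = np.diff(values[np.isfinite(values)], 2)
    if d2.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d2 - np.median(d2)))) / math.sqrt(6.0)


def detect_peaks(
    profile: Profile,
    fit_window: float = DEFAULT_FIT_WINDOW,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    prominence_factor: float = 4.0,
) -> list[float]:
    """Peak positions [bp] by sliding parabolic fits.

    A parabola is fitted to every continuous stretch of ``fit_window``
    (12 points at 2.5 kb); concave fits whose vertex falls inside the
    stretch yield candidate peaks.  Candidates must rise above
    ``threshold_frac`` times the profile average and be locally prominent:
    the fitted drop from vertex to window edge must exceed
    ``prominence_factor`` times the profile's robust point noise, which
    rejects both flat noise (no coherent curvature) and smooth large-scale
    structure (strong values but negligible curvature on the window
    scale).  Candidates closer than one window are merged (highest fitted
    peak kept; ties resolved leftmost).
    """
    pos, val = profile.positions, profile.values
    n = pos.size
    if n < 2:
        raise ValueError("profile too short")
    step = float(np.median(np.diff(pos)))
    w = max(int(round(fit_window / step)), 3)
    if w > n:
        raise ValueError(f"fit window of {w} points exceeds profile length {n}")
    mean_val = float(np.nanmean(val))
    sigma = _roughness(val)
    candidates: list[tuple[float, float]] = []  # (position, fitted height)
    for i0 in range(0, n - w + 1):
        x = pos[i0 : i0 + w]
        y = val[i0 : i0 + w]
        good = np.isfinite(y)
        if good.sum() < 3:
            continue
        xc = x - x.mean()
        a, b, c = np.polyfit(xc[good], y[good], 2)
        if a >= 0:
            continue  # not concave: no interior maximum
        xv = -b / (2.0 * a)
        if xv < xc[0] or xv > xc[-1]:
            continue
        height = a * xv * xv + b * xv + c
        prominence = -a * (fit_window / 2.0) ** 2
        # absolute floor guards against float noise on perfectly smooth input
        if prominence <= prominence_factor * sigma + 1e-9 * abs(mean_val):
            continue
        candidates.append((float(xv + x.mean()), float(height)))
    accepted = [(p, h) for p, h in candidates if h > threshold_frac * mean_val]
    # merge candidates within one fit window, keep the highest (leftmost on tie)
    accepted.sort(key=lambda t: t[0])
    peaks: list[tuple[float, float]] = []
    cluster: list[tuple[float, float]] = []
    merge_radius = fit_window

    def flush():
        if cluster:
            best = max(cluster, key=lambda t: (t[1], -t[0]))
            peaks.append(best)

    for p, h in accepted:
        if cluster and p - cluster[-1][0] > merge_radius:
            flush()
            cluster = []
        cluster.append((p, h))
    flush()
    return [p for p, _ in peaks]


def local_projection(
    domain_map: ContactMap,
    anchor: float,
    halfwidth: float = DEFAULT_LOCAL_HALFWIDTH,
) -> Profile:
    """Mean over the row band of ``+-halfwidth`` bp around an anchor site,
    excluding masked bins; rejected if the whole band is masked."""
    i = domain_map.bin_of(anchor)
    if i < 0 or i >= domain_map.n_bins:
        raise ValueError(f"anchor {anchor} outside domain")
    k = max(int(halfwidth // domain_map.bin_size), 0)
    rows = domain_map.matrix[max(i - k, 0) : i + k + 1]
    if np.all(np.isnan(rows)):
        raise ValueError("anchor band is fully masked")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(rows, axis=0)
    return Profile(_positions(domain_map), values, kind="local", anchor=float(anchor))


def call_loop_bases(
    domain_map: ContactMap,
    fit_window: float = DEFAULT_FIT_WINDOW,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    local_halfwidth: float = DEFAULT_LOCAL_HALFWIDTH,
) -> list[LoopCall]:
    """Two-direction loop-base calling.

    Global-profile peaks serve as anchors; each anchor's local projection
    is peak-searched for partner sites.  A pair recovered from both of its
    anchors (coordinates agreeing within one fit window) is high
    confidence; a one-directional pair is low confidence.  The returned
    list is deduplicated with ``site_i < site_j``.
    """
    anchors = detect_peaks(global_profile(domain_map), fit_window, threshold_frac)
    directed: list[tuple[float, float]] = []
    for a in anchors:
        try:
            prof = local_projection(domain_map, a, local_halfwidth)
        except ValueError:
            continue
        for partner in detect_peaks(prof, fit_window, threshold_frac):
            directed.append((a, partner))
    calls: list[LoopCall] = []
    used = [False] * len(directed)
    for idx, (a, b) in enumerate(directed):
        if used[idx]:
            continue
        used[idx] = True
        confidence = "low"
        best_match = None
        for jdx in range(idx + 1, len(directed)):
            if used[jdx]:
                continue
            a2, b2 = directed[jdx]
            # reciprocal: the second direction anchors near b and points near a
            if abs(a2 - b) <= fit_window and abs(b2 - a) <= fit_window:
                best_match = jdx
                break
        if best_match is not None:
            used[best_match] = True
            confidence = "high"
        lo, hi = sorted((a, b))
        if hi - lo <= fit_window:
            continue  # self-pair within resolution
        calls.append(LoopCall(lo, hi, confidence))
    # deduplicate overlapping calls, preferring high confidence
    calls.sort(key=lambda c: (c.site_i, c.site_j, c.confidence != "high"))
    deduped: list[LoopCall] = []
    for c in calls:
        dup = False
        for d in deduped:
            if abs(c.site_i - d.site_i) <= fit_window and abs(c.site_j - d.site_j) <= fit_window:
                dup = True
                break
        if not dup:
            deduped.append(c)
    return deduped
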