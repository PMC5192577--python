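"""Static vs dynamic accessible volume of a chromatin domain.

A probe of radius ``r_p`` cannot enter the dilated volume of the chromatin
fiber (length ``L``, diameter ``d_f``) threading the domain.  On the
millisecond time scale a single scarce molecule sees a static snapshot of
the domain (volume ``V``); abundant molecules are adiabatically replenished
into the fluctuation-expanded volume ``V_dyn``, which is of the same order
as the domain volume itself (default 2 V).  Accessibility is the accessible
volume fraction of a cylinder-dilation model:

    A(r_p) = max(0, 1 - L pi (d_f/2 + r_p)^2 / V_mode)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AccessibilityModel", "accessible_fraction", "accessibility_limit"]


@dataclass(frozen=True)
class AccessibilityModel:
    """Domain geometry for the accessibility calculation.

    V : static domain volume [um^3]
    V_dyn : fluctuation-expanded volume [um^3], >= V
    L : chromatin fiber contour length inside the domain [nm]
    d_f : effective fiber diameter [nm]
    """

    V: float
    L: float
    V_dyn: float | None = None
    d_f: float = 14.0

    def __post_init__(self) -> None:
        if self.V_dyn is None:
            object.__setattr__(self, "V_dyn", 2.0 * self.V)
        if not (self.V > 0 and self.L > 0 and self.d_f > 0):
            raise ValueError("V, L and d_f must be positive")
        if self.V_dyn < self.V:
            raise ValueError("V_dyn must be >= V")

    def _volume(self, mode: str) -> float:
        if mode == "static":
            return self.V
        if mode == "dynamic":
            return self.V_dyn
        raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")


def accessible_fraction(
    model: AccessibilityModel, r_p: float | np.ndarray, mode: str = "static"
) -> float | np.ndarray:
    """Accessible volume fraction for probes of radius ``r_p`` [nm]."""
    V_nm3 = model._volume(mode) * 1e9  # um^3 -> nm^3
    r = np.asarray(r_p, dtype=float)
    if np.any(r < 0):
        raise ValueError("probe radius must be non-negative")
    occluded = model.L * math.pi * (model.d_f / 2.0 + r) ** 2
    A = np.clip(1.0 - occluded / V_nm3, 0.0, 1.0)
    return float(A) if np.isscalar(r_p) else A


def accessibility_limit(model: AccessibilityModel, mode: str = "static") -> float:
    """Probe radius [nm] at which accessibility drops to 50 %.

    Closed form r_50 = sqrt(V_mode / (2 pi L)) - d_f/2.  If even a point
    probe sees less than half the volume accessible the limit is undefined
    and 0 is returned.
    """
    if accessible_fraction(model, 0.0, mode) <= 0.5:
        return 0.0
    V_nm3 = model._volume(mode) * 1e9
    return math.sqrt(V_nm3 / (2.0 * math.pi * model.L)) - model.d_f / 2.0
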