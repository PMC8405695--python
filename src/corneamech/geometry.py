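"""Thin-shell loading geometry and stress/strain conversions.

The cornea is treated as a pressurised thin spherical shell.  Under a
pressure modulation ``Δp`` the membrane (hoop) stress changes by Laplace's
law ``Δσ = Δp·R/(2·cct)``; in the extensometry mount the same shell theory
converts an indenter force ``F`` applied over a clamped circular aperture
into a tensile stress ``σ = F/(2π·R·cct)`` and the indenter travel ``Δl``
into a 2-D tensile strain via the arc-length-over-chord stretch of a
spherical cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: Conversion factor from mmHg to pascal.
MMHG_TO_PA = 133.322

#: Largest strain the arc-chord relation can represent (Δl = R): π/2 − 1.
STRAIN_CEILING = np.pi / 2.0 - 1.0


@dataclass(frozen=True)
class LoadingGeometry:
    """Geometry of a corneal loading experiment.

    Parameters
    ----------
    cct_um : float
        Central corneal thickness in micrometres.
    radius_mm : float
        Radius entering the stress/strain formulas, in millimetres.  For
        whole-globe inflation this is the corneal radius of curvature
        (1.5 mm); for the extensometry mount it is the holder-aperture
        radius (0.8 mm, from a 1.6 mm diameter central opening).
    delta_p_mmhg : float, optional
        Ambient pressure modulation in mmHg (inflation loading only).
        Negative values denote a pressure reduction.
    """

    cct_um: float
    radius_mm: float = 1.5
    delta_p_mmhg: float | None = None

    def __post_init__(self) -> None:
        if not self.cct_um > 0:
            raise ValueError(f"cct_um must be positive, got {self.cct_um}")
        if not self.radius_mm > 0:
            raise ValueError(f"radius_mm must be positive, got {self.radius_mm}")


def laplace_stress(geometry: LoadingGeometry) -> float:
    """Membrane stress change (Pa) of a thin shell under pressure modulation.

    Implements ``Δσ = Δp·R/(2·cct)`` with Δp converted at 133.322 Pa/mmHg.
    The sign of the returned stress follows the sign of ``delta_p_mmhg``.
    """
    if geometry.delta_p_mmhg is None:
        raise ValueError("LoadingGeometry.delta_p_mmhg is required for laplace_stress")
    dp_pa = geometry.delta_p_mmhg * MMHG_TO_PA
    return dp_pa * (geometry.radius_mm * 1e-3) / (2.0 * geometry.cct_um * 1e-6)


def stress_from_force(force_n, geometry: LoadingGeometry):
    """Tensile stress (Pa) induced by an indenter force over a clamped aperture.

    Implements ``σ = F/(2π·R·cct)``.  ``force_n`` may be a scalar or array.
    """
    denom = 2.0 * np.pi * (geometry.radius_mm * 1e-3) * (geometry.cct_um * 1e-6)
    return np.asarray(force_n, dtype=float) / denom if np.ndim(force_n) else float(force_n) / denom


def strain_from_travel(dl_um, radius_mm: float = 0.8, form: str = "arcsin"):
    """2-D tensile strain from indenter axial travel Δl.

    The deformed cornea is modelled as a spherical cap over the clamped
    aperture of radius ``R``; the chord (aperture diameter) is stretched to
    the cap arc.  With the cap circumradius ``r = (Δl² + R²)/(2Δl)`` the
    stretch is ``ε = (r/R)·arcsin(R/r) − 1``: zero at Δl = 0, positive and
    strictly increasing up to Δl = R where it reaches π/2 − 1.

    ``form="printed"`` evaluates the sin-variant ``(r/R)·sin(R/r) − 1``
    instead, which is negative for small Δl; it is retained only for
    comparison and should not be used for analysis.

    Parameters
    ----------
    dl_um : scalar or array
        Axial travel in micrometres; must be non-negative.
    radius_mm : float
        Aperture radius in millimetres.
    """
    dl = np.asarray(dl_um, dtype=float) * 1e-3  # -> mm
    scalar = dl.ndim == 0
    dl = np.atleast_1d(dl)
    if np.any(dl < 0):
        raise ValueError("travel must be non-negative")
    if form not in ("arcsin", "printed"):
        raise ValueError(f"unknown form {form!r}")
    R = float(radius_mm)
    eps = np.zeros_like(dl)
    nz = dl > 0
    r = (dl[nz] ** 2 + R**2) / (2.0 * dl[nz])
    ratio = np.clip(R / r, -1.0, 1.0)
    if form == "arcsin":
        eps[nz] = (r / R) * np.arcsin(ratio) - 1.0
    else:
        eps[nz] = (r / R) * np.sin(ratio) - 1.0
    return float(eps[0]) if scalar else eps


def travel_from_strain(eps, radius_mm: float = 0.8):
    """Invert :func:`strain_from_travel` (arcsin form) numerically.

    Valid for 0 ≤ ε < π/2 − 1 (the Δl = R ceiling); returns travel in μm.
    """
    eps_arr = np.atleast_1d(np.asarray(eps, dtype=float))
    if np.any(eps_arr < 0) or np.any(eps_arr >= STRAIN_CEILING):
        raise ValueError(
            f"strain must lie in [0, {STRAIN_CEILING:.4f}) for travel inversion"
        )
    r_um = radius_mm * 1e3
    out = np.zeros_like(eps_arr)
    for i, e in enumerate(eps_arr):
        if e == 0.0:
            continue
        out[i] = brentq(
            lambda dl: strain_from_travel(dl, radius_mm) - e,
            1e-9, r_um, xtol=1e-12, rtol=8.9e-16,
        )
    return float(out[0]) if np.ndim(eps) == 0 else out
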