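"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three measurement streams:

* speckle-carrying complex OCT B-scan pairs of a curved corneal layer with
  a uniform imposed axial strain encoded as a depth-cumulative phase ramp
  (:func:`gen_oct_pair`),
* stress-relaxation and tensile-ramp force traces forward-evaluated from a
  Prony series / target window slope (:func:`gen_relaxation_trace`,
  :func:`gen_ramp_trace`, :func:`gen_protocol_trace`), and
* two-group per-eye cohort tables drawn from normal distributions
  (:func:`gen_cohort`).

All generators are deterministic under a fixed seed.  Module-level
constants hold the study conditions used throughout: the published group
means/SDs and Prony constants of wild-type (wt) and collagen-V
haploinsufficient (Col5a1+/-) mouse corneas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .extensometry import ForceTrace, PronyModel
from .geometry import (
    STRAIN_CEILING,
    LoadingGeometry,
    stress_from_force,
    travel_from_strain,
)
from .oce import OCEScanPair


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a speckle B-scan phantom.

    The phantom is a curved layer (circular-arc anterior/posterior
    boundaries, apex thickness ``cct_um``, radius of curvature
    ``radius_mm``) of fully developed speckle — complex circular-Gaussian
    reflectivity per pixel — on a zero background.  The deformed scan is
    the reference with a depth-cumulative phase shift corresponding to a
    uniform axial strain, plus optional additive complex white Gaussian
    noise at ``snr_db``.
    """

    cct_um: float = 148.0
    radius_mm: float = 1.5
    imposed_strain: float = -4.93e-3
    n_ascans: int = 1000
    asu_um: float = 4.48
    wavelength_nm: float = 878.0
    refractive_index: float = 1.375
    snr_db: float | None = None
    seed: int = 0
    # imaging-grid details not fixed by the published optics
    n_z: int = 160
    lsu_um: float = 12.5
    apex_depth_px: int = 30
    delta_p_mmhg: float = -3.0

    def __post_init__(self) -> None:
        if not self.cct_um > 0:
            raise ValueError("cct_um must be positive")
        if self.n_ascans < 1:
            raise ValueError("n_ascans must be >= 1")
        if not self.asu_um > 0:
            raise ValueError("asu_um must be positive")
        limit = self.strain_limit
        if abs(self.imposed_strain) >= limit:
            raise ValueError(
                f"imposed strain {self.imposed_strain:+.4g} exceeds the "
                f"phase-unambiguous range ±{limit:.4g} "
                "(= wavelength / (4·n·asu))"
            )

    @property
    def strain_limit(self) -> float:
        """Phase-unambiguous strain bound λ/(4·n·asu)."""
        return (self.wavelength_nm * 1e-3) / (
            4.0 * self.refractive_index * self.asu_um
        )


def gen_oct_pair(spec: PhantomSpec) -> OCEScanPair:
    """Generate a reference/deformed complex B-scan pair.

    The per-pixel phase step inside tissue is ``4π·n·asu·ε/λ`` so that the
    depth-adjacent conjugate-product strain estimator recovers the imposed
    strain exactly on noiseless data.  Ground truth (imposed strain, the
    grid-quantised thickness, the tissue mask) is attached as
    ``pair.truth``.
    """
    rng = np.random.default_rng(spec.seed)
    nz, nx = spec.n_z, spec.n_ascans
    lam_um = spec.wavelength_nm * 1e-3
    n = spec.refractive_index

    thickness_px = int(round(spec.cct_um * n / spec.asu_um))
    if thickness_px < 2:
        raise ValueError("phantom thinner than two axial pixels")

    x_um = (np.arange(nx) - (nx - 1) / 2.0) * spec.lsu_um
    r_um = spec.radius_mm * 1e3
    inside = np.abs(x_um) < r_um
    sagitta = np.full(nx, np.inf)
    sagitta[inside] = r_um - np.sqrt(r_um**2 - x_um[inside] ** 2)
    anterior = np.full(nx, -1, dtype=int)
    ok = inside & (sagitta / spec.asu_um + spec.apex_depth_px + thickness_px < nz)
    anterior[ok] = np.round(spec.apex_depth_px + sagitta[ok] / spec.asu_um).astype(int)

    mask = np.zeros((nz, nx), dtype=bool)
    depth = np.zeros((nz, nx))  # depth below the anterior surface, in px
    zidx = np.arange(nz)[:, None]
    cols = np.nonzero(ok)[0]
    ant = anterior[cols]
    colmask = (zidx >= ant[None, :]) & (zidx < ant[None, :] + thickness_px)
    mask[:, cols] = colmask
    depth[:, cols] = np.where(colmask, zidx - ant[None, :], 0.0)

    refl = np.zeros((nz, nx), dtype=complex)
    nt = int(mask.sum())
    refl[mask] = (rng.standard_normal(nt) + 1j * rng.standard_normal(nt)) / np.sqrt(2)

    phase_per_px = 4.0 * np.pi * n * spec.asu_um * spec.imposed_strain / lam_um
    b_ref = refl
    b_def = refl * np.exp(1j * phase_per_px * depth)

    if spec.snr_db is not None:
        sd = np.sqrt(10.0 ** (-spec.snr_db / 10.0) / 2.0)
        b_ref = b_ref + sd * (
            rng.standard_normal((nz, nx)) + 1j * rng.standard_normal((nz, nx))
        )
        b_def = b_def + sd * (
            rng.standard_normal((nz, nx)) + 1j * rng.standard_normal((nz, nx))
        )

    meta = {
        "wavelength_nm": spec.wavelength_nm,
        "asu_um": spec.asu_um,
        "lsu_um": spec.lsu_um,
        "refractive_index": spec.refractive_index,
        "n_ascans": spec.n_ascans,
        "n_z": spec.n_z,
        "delta_p_mmhg": spec.delta_p_mmhg,
        "radius_mm": spec.radius_mm,
        "snr_db": spec.snr_db,
        "seed": spec.seed,
    }
    truth = {
        "imposed_strain": spec.imposed_strain,
        "cct_um": spec.cct_um,
        "cct_um_grid": thickness_px * spec.asu_um / n,
        "tissue_mask": mask,
        "anterior": anterior,
    }
    return OCEScanPair(b_ref=b_ref, b_def=b_def, meta=meta, truth=truth)


@dataclass(frozen=True)
class TraceSpec:
    """Specification of a synthetic stress-relaxation trace."""

    prony: PronyModel
    eps0: float = 0.18
    sample_rate_hz: float = 10.0
    duration_s: float = 120.0
    noise_sd_rel: float = 0.0
    seed: int = 0
    geometry: LoadingGeometry = field(
        default_factory=lambda: LoadingGeometry(cct_um=148.0, radius_mm=0.8)
    )

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if not 0 < self.eps0 < STRAIN_CEILING:
            raise ValueError(
                f"eps0 must lie in (0, {STRAIN_CEILING:.4f}) to be reachable "
                "by indenter travel"
            )


def gen_relaxation_trace(spec: TraceSpec) -> ForceTrace:
    """Forward-evaluate σ(t) = ε₀·E(t) and convert to a force trace.

    Noise is additive Gaussian on the stress with SD equal to
    ``noise_sd_rel`` times the initial stress.  Indenter travel is the
    constant value realising ε₀ through the arc-chord relation.
    """
    dt = 1.0 / spec.sample_rate_hz
    t = np.arange(0.0, spec.duration_s + dt / 2.0, dt)
    sigma = spec.prony.stress(t, spec.eps0)
    if spec.noise_sd_rel > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = sigma + rng.normal(0.0, spec.noise_sd_rel * sigma[0], t.size)
    g = spec.geometry
    denom = 2.0 * np.pi * (g.radius_mm * 1e-3) * (g.cct_um * 1e-6)
    force = np.maximum(sigma * denom, 0.0)
    travel = np.full(t.size, travel_from_strain(spec.eps0, g.radius_mm))
    labels = np.array(["relaxation"] * t.size, dtype=object)
    return ForceTrace(t, force, travel, labels, g)


def gen_ramp_trace(
    target_modulus_pa: float,
    geometry: LoadingGeometry,
    f_start: float = 0.4,
    f_end: float = 4.0,
    rate_n_per_s: float = 0.3,
    seed: int | None = None,
    eps_max: float = 0.20,
    n_samples: int = 1200,
    noise_sd_rel: float = 0.0,
) -> ForceTrace:
    """Tensile ramp whose stress–strain slope equals ``target_modulus_pa``.

    Strain ramps linearly from 0 to ``eps_max`` (default 0.20, covering the
    10–15% analysis window) while stress is affine in strain with the
    target slope, starting from the stress at ``f_start``.  Travel is the
    exact arc-chord inverse of the strain, and time follows the force rate.
    The trace ends at ``eps_max`` — typically well before ``f_end`` — since
    the arc-chord relation caps representable strain at π/2 − 1.
    """
    if not f_start < f_end:
        raise ValueError("f_start must be below f_end")
    if not 0 < eps_max < STRAIN_CEILING:
        raise ValueError(f"eps_max must lie in (0, {STRAIN_CEILING:.4f})")
    if target_modulus_pa <= 0:
        raise ValueError("target modulus must be positive")
    g = geometry  # LoadingGeometry validates cct > 0 on construction
    denom = 2.0 * np.pi * (g.radius_mm * 1e-3) * (g.cct_um * 1e-6)
    sigma_start = f_start / denom
    eps = np.linspace(0.0, eps_max, n_samples)
    sigma = sigma_start + target_modulus_pa * eps
    force = sigma * denom
    force = np.minimum(force, f_end)
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        force = np.maximum(force + rng.normal(0.0, noise_sd_rel * f_start, eps.size), 0.0)
    t = (np.linspace(0.0, eps_max, n_samples) * target_modulus_pa * denom) / rate_n_per_s
    # ensure strictly increasing time even for tiny moduli
    if t[-1] <= 0 or np.any(np.diff(t) <= 0):
        t = np.linspace(0.0, max(eps_max, 1e-3), n_samples)
    travel = travel_from_strain(eps, g.radius_mm)
    labels = np.array(["ramp"] * eps.size, dtype=object)
    return ForceTrace(t, force, travel, labels, g)


def gen_protocol_trace(
    spec: TraceSpec,
    ramp_modulus_pa: float = 30.7e3,
    cycle_period_s: float = 4.0,
    n_cycles: int = 3,
    ramp_eps_span: float = 0.2,
    ramp_duration_s: float = 12.0,
    rupture_at_eps: float | None = None,
) -> ForceTrace:
    """Full three-phase protocol trace with ground-truth segment labels.

    Pre-conditioning: ``n_cycles`` triangular force cycles between 0.04 and
    0.4 N followed by a reload to 0.4 N.  Relaxation: ``spec.duration_s``
    of Prony-series stress decay at constant travel, starting at the reload
    peak.  Ramp: strain rises linearly from ε₀ by ``ramp_eps_span`` with
    stress affine at slope ``ramp_modulus_pa``.  If ``rupture_at_eps`` is
    given the force collapses to 5% of its running value at that strain
    (labels remain "ramp"; detection is the analysis module's job).
    """
    g = spec.geometry
    denom = 2.0 * np.pi * (g.radius_mm * 1e-3) * (g.cct_um * 1e-6)
    dt = 1.0 / spec.sample_rate_hz
    e0 = spec.prony.e0_pa

    # --- pre-conditioning cycles + reload, force-programmed ---
    half = max(int(round(cycle_period_s / 2.0 / dt)), 2)
    rise = np.linspace(0.04, 0.4, half, endpoint=False)
    fall = np.linspace(0.4, 0.04, half, endpoint=False)
    cycles = np.concatenate([np.concatenate([rise, fall])] * n_cycles)
    reload_ = np.linspace(0.04, 0.4, half, endpoint=False)
    f_pre = np.concatenate([cycles, reload_])
    # quasi-elastic travel response during pre-conditioning
    eps_pre = np.clip(f_pre / denom / e0, 0.0, 0.99 * STRAIN_CEILING)
    dl_pre = travel_from_strain(eps_pre, g.radius_mm)

    # --- relaxation at constant travel ---
    t_rel = np.arange(0.0, spec.duration_s + dt / 2.0, dt)
    sigma_rel = spec.prony.stress(t_rel, spec.eps0)
    if spec.noise_sd_rel > 0:
        rng = np.random.default_rng(spec.seed)
        sigma_rel = sigma_rel + rng.normal(
            0.0, spec.noise_sd_rel * sigma_rel[0], t_rel.size
        )
    f_rel = np.maximum(sigma_rel * denom, 0.0)
    f_rel[0] = max(f_rel[0], 0.4)  # reload peak defines the plateau start
    dl_rel = np.full(t_rel.size, travel_from_strain(spec.eps0, g.radius_mm))

    # --- rupture ramp, strain-programmed from eps0 upward ---
    n_ramp = max(int(round(ramp_duration_s / dt)), 10)
    eps_ramp = spec.eps0 + np.linspace(0.0, ramp_eps_span, n_ramp + 1)[1:]
    eps_ramp = np.clip(eps_ramp, 0.0, 0.999 * STRAIN_CEILING)
    sigma_ramp = sigma_rel[-1] + ramp_modulus_pa * (eps_ramp - spec.eps0)
    f_ramp = sigma_ramp * denom
    if rupture_at_eps is not None:
        broke = eps_ramp >= rupture_at_eps
        if broke.any():
            k = int(np.argmax(broke))
            f_ramp[k:] = 0.05 * f_ramp[max(k - 1, 0)]
    dl_ramp = travel_from_strain(eps_ramp, g.radius_mm)

    force = np.concatenate([f_pre, f_rel, f_ramp])
    travel = np.concatenate([dl_pre, dl_rel, dl_ramp])
    t = np.arange(force.size) * dt
    labels = np.array(
        ["precondition"] * f_pre.size
        + ["relaxation"] * f_rel.size
        + ["ramp"] * f_ramp.size,
        dtype=object,
    )
    return ForceTrace(t, force, travel, labels, g)


@dataclass(frozen=True)
class GroupSpec:
    """Normal-distribution parameters of one cohort group."""

    label: str
    n_eyes: int
    cct_mean_sd: tuple[float, float]
    strain_mean_sd: tuple[float, float]  # permil
    modulus_mean_sd: tuple[float, float]  # OCE modulus, kPa
    ext_modulus_mean_sd: tuple[float, float] | None = None  # extensometry, kPa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be >= 2")
        sds = [self.cct_mean_sd[1], self.strain_mean_sd[1], self.modulus_mean_sd[1]]
        if self.ext_modulus_mean_sd is not None:
            sds.append(self.ext_modulus_mean_sd[1])
        if any(sd < 0 for sd in sds):
            raise ValueError("all SDs must be >= 0")


def gen_cohort(groups: list[GroupSpec]) -> pd.DataFrame:
    """Per-eye cohort table drawn from the stated normal distributions.

    Columns: ``eye_id, group, cct_um, strain_permil, E_oct_kPa, E_ext_kPa``.
    """
    if not groups:
        raise ValueError("at least one GroupSpec is required")
    rows = []
    for g in groups:
        rng = np.random.default_rng(g.seed)
        cct = rng.normal(*g.cct_mean_sd, g.n_eyes)
        strain = rng.normal(*g.strain_mean_sd, g.n_eyes)
        e_oct = rng.normal(*g.modulus_mean_sd, g.n_eyes)
        ext = g.ext_modulus_mean_sd or (np.nan, 0.0)
        e_ext = rng.normal(ext[0], ext[1], g.n_eyes) if g.ext_modulus_mean_sd else np.full(g.n_eyes, np.nan)
        for i in range(g.n_eyes):
            rows.append(
                {
                    "eye_id": f"{g.label}_{i + 1:02d}",
                    "group": g.label,
                    "cct_um": cct[i],
                    "strain_permil": strain[i],
                    "E_oct_kPa": e_oct[i],
                    "E_ext_kPa": e_ext[i],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Study conditions: published group statistics and Prony constants.
# --------------------------------------------------------------------------

#: Wild-type 3-term Prony constants (Pa / s).
WT_PRONY = PronyModel(
    e_inf_pa=1.18e6,
    terms=[(0.43e6, 3.1), (0.51e6, 51.0), (0.88e6, 124.0)],
)

#: Col5a1+/- 3-term Prony constants (Pa / s).
COL5A1_PRONY = PronyModel(
    e_inf_pa=1.14e6,
    terms=[(0.50e6, 3.1), (0.62e6, 56.0), (1.29e6, 57.0)],
)

#: Wild-type cohort statistics (mean, SD).
WT_GROUP = GroupSpec(
    label="wt",
    n_eyes=14,
    cct_mean_sd=(148.0, 10.0),
    strain_mean_sd=(-4.93, 1.92),
    modulus_mean_sd=(430.0, 103.0),
    ext_modulus_mean_sd=(21.5, 5.7),
    seed=0,
)

#: Col5a1+/- cohort statistics (mean, SD).
COL5A1_GROUP = GroupSpec(
    label="col5a1",
    n_eyes=14,
    cct_mean_sd=(125.0, 11.0),
    strain_mean_sd=(-4.84, 1.99),
    modulus_mean_sd=(506.0, 88.0),
    ext_modulus_mean_sd=(30.7, 12.1),
    seed=1,
)


def group_spec_with(base: GroupSpec, **changes) -> GroupSpec:
    """Convenience: a copy of a GroupSpec with fields replaced."""
    return replace(base, **changes)
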