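"""2D extensometry: stress relaxation, Prony-series fitting, ramp modulus.

A corneal button clamped over a circular aperture is loaded by a
hemispherical indenter through a three-step protocol: (1) three
pre-conditioning force cycles between 0.04 and 0.4 N, (2) a 120 s stress
relaxation at an initial load of 0.4 N, and (3) a rupture ramp from 0.4
towards 4 N.  Force converts to tensile stress via thin-shell theory
(σ = F/(2π·R·cct)) and indenter travel to 2-D strain via the spherical-cap
arc-chord relation (see :mod:`corneamech.geometry`).

Viscoelasticity is summarised two ways: the percent stress reduction after
100 s of relaxation, and a 3-term Prony series

    E(t) = E∞ + Σᵢ Eᵢ · exp(−t/τᵢ)

fitted to σ(t) = ε₀·E(t) by constrained least squares (all moduli and time
constants positive).  The fit uses variable projection — non-negative
least squares for the moduli at fixed time constants, nested inside a
bounded optimisation over log τ with multi-start initialisation — because
exponential-sum fitting is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .geometry import LoadingGeometry, stress_from_force, strain_from_travel

SEGMENT_LABELS = ("precondition", "relaxation", "ramp")
#: Instantaneous force drop (fraction of running max) that flags rupture.
RUPTURE_DROP_FRACTION = 0.5


@dataclass
class ForceTrace:
    """Force–time–travel record of an extensometry run.

    ``segment`` labels each sample as precondition/relaxation/ramp (may be
    None before :func:`split_protocol`).  ``geometry`` carries the aperture
    radius and the OCT-measured thickness used for stress conversion.
    """

    t_s: np.ndarray
    force_n: np.ndarray
    travel_um: np.ndarray
    segment: np.ndarray | None = None
    geometry: LoadingGeometry | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.travel_um = np.asarray(self.travel_um, dtype=float)
        if not (self.t_s.shape == self.force_n.shape == self.travel_um.shape):
            raise ValueError("t, force and travel must have identical shape")
        if self.t_s.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time samples must be strictly increasing")
        if np.any(self.force_n < 0):
            raise ValueError("force must be non-negative")
        if self.segment is not None:
            self.segment = np.asarray(self.segment, dtype=object)
            if self.segment.shape != self.t_s.shape:
                raise ValueError("segment labels must match sample count")

    def __len__(self) -> int:
        return self.t_s.size

    def select(self, label: str) -> "ForceTrace":
        """Sub-trace of one protocol segment."""
        if self.segment is None:
            raise ValueError("trace has no segment labels; run split_protocol")
        m = self.segment == label
        if not m.any():
            raise ValueError(f"no samples labelled {label!r}")
        return ForceTrace(
            self.t_s[m], self.force_n[m], self.travel_um[m],
            self.segment[m], self.geometry,
        )

    def to_frame(self) -> pd.DataFrame:
        seg = self.segment if self.segment is not None else [""] * len(self)
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "force_N": self.force_n,
                "travel_um": self.travel_um,
                "segment": seg,
            }
        )


@dataclass
class StressStrainCurve:
    """Paired tensile stress (Pa) and strain samples."""

    sigma_pa: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        self.sigma_pa = np.asarray(self.sigma_pa, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.sigma_pa.shape != self.eps.shape:
            raise ValueError("sigma and eps must have identical shape")
        if np.any(self.eps < 0):
            raise ValueError("strain must be non-negative")


@dataclass
class PronyModel:
    """Prony-series relaxation modulus E(t) = E∞ + Σ Eᵢ·exp(−t/τᵢ).

    ``e_inf_pa`` is the long-term modulus (full relaxation); ``terms`` are
    (Eᵢ [Pa], τᵢ [s]) pairs, kept sorted by ascending time constant.
    """

    e_inf_pa: float
    terms: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.e_inf_pa > 0:
            raise ValueError("long-term modulus must be positive")
        for e_i, tau_i in self.terms:
            if e_i < 0:
                raise ValueError("Prony moduli must be non-negative")
            if not tau_i > 0:
                raise ValueError("Prony time constants must be positive")
        self.terms = sorted(self.terms, key=lambda et: et[1])

    @property
    def e0_pa(self) -> float:
        """Instantaneous modulus E(0) = E∞ + Σ Eᵢ."""
        return self.e_inf_pa + sum(e for e, _ in self.terms)

    def modulus(self, t_s):
        """Relaxation modulus E(t) in Pa."""
        t = np.asarray(t_s, dtype=float)
        e = np.full_like(t, self.e_inf_pa, dtype=float)
        for e_i, tau_i in self.terms:
            e = e + e_i * np.exp(-t / tau_i)
        return e if t.ndim else float(e)

    def stress(self, t_s, eps0: float):
        """Relaxation stress σ(t) = ε₀·E(t) in Pa."""
        return eps0 * self.modulus(t_s)

    def reduction_pct(self, horizon_s: float = 100.0) -> float:
        """Closed-form percent stress reduction over ``horizon_s``."""
        e0 = self.e0_pa
        return 100.0 * (e0 - self.modulus(horizon_s)) / e0


@dataclass
class RelaxationResult:
    """Relaxation summary: 100 s reduction, fitted Prony model, residual."""

    reduction_pct: float
    prony: PronyModel
    fit_rss: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.reduction_pct <= 100.0:
            raise ValueError("reduction_pct must lie in [0, 100]")


class PronyFitError(RuntimeError):
    """Raised when no multi-start candidate converges; carries the best try."""

    def __init__(self, message: str, best: PronyModel | None = None):
        super().__init__(message)
        self.best = best


def curve_from_trace(trace: ForceTrace, form: str = "arcsin") -> StressStrainCurve:
    """Convert a force/travel trace to stress/strain using its geometry."""
    if trace.geometry is None:
        raise ValueError("trace has no LoadingGeometry attached")
    sigma = stress_from_force(trace.force_n, trace.geometry)
    eps = strain_from_travel(trace.travel_um, trace.geometry.radius_mm, form=form)
    return StressStrainCurve(np.atleast_1d(sigma), np.atleast_1d(eps))


def detect_rupture(trace: ForceTrace) -> int | None:
    """Index of the first instantaneous force drop >50% of the running max."""
    f = trace.force_n
    if f.size < 2:
        return None
    running = np.maximum.accumulate(f)
    drop = running[:-1] - f[1:]
    hits = np.nonzero(drop > RUPTURE_DROP_FRACTION * running[:-1])[0]
    return int(hits[0] + 1) if hits.size else None


def split_protocol(trace: ForceTrace) -> ForceTrace:
    """Assign precondition/relaxation/ramp labels from the force program.

    The relaxation segment is the longest run of non-increasing force that
    starts at a local force maximum near the holding load; everything
    before it is pre-conditioning and the persistent force rise after it is
    the rupture ramp.  The relaxation clock is re-zeroed at the plateau
    start.  If no plateau is found the trace is returned with ramp-only
    labels and relaxation analyses must refuse it.
    """
    f = trace.force_n
    n = f.size
    df = np.diff(f)
    # runs of non-increasing force lasting at least 20 samples or 5 s
    min_len = max(20, int(0.02 * n))
    runs: list[tuple[int, int]] = []
    start = None
    for i in range(df.size):
        if df[i] <= 0:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i))
                start = None
    if start is not None:
        runs.append((start, df.size))
    # a plateau must start near the highest force seen so far (running max),
    # so later ramp forces cannot disqualify it
    runs = [
        (a, b)
        for a, b in runs
        if b - a >= min_len and f[a] >= 0.8 * f[: a + 1].max()
    ]

    labels = np.array(["ramp"] * n, dtype=object)
    t = trace.t_s
    if runs:
        a, b = max(runs, key=lambda ab: ab[1] - ab[0])
        labels[:a] = "precondition"
        labels[a : b + 1] = "relaxation"
        labels[b + 1 :] = "ramp"
        t = t.copy() - t[a]  # re-zero the relaxation clock
    return ForceTrace(t, f, trace.travel_um, labels, trace.geometry)


def relaxation_reduction(
    sigma_pa: np.ndarray, t_s: np.ndarray, horizon_s: float = 100.0
) -> float:
    """Percent stress reduction ``100·(σ(t₀) − σ(t₀+h))/σ(t₀)``.

    σ(t₀) is the first post-load sample of the relaxation segment; the
    stress at the horizon is linearly interpolated.
    """
    sigma = np.asarray(sigma_pa, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if t[-1] - t[0] < horizon_s:
        raise ValueError(
            f"trace spans {t[-1] - t[0]:.1f} s < horizon {horizon_s:.1f} s"
        )
    s0 = sigma[0]
    sh = float(np.interp(t[0] + horizon_s, t, sigma))
    return 100.0 * (s0 - sh) / s0


def _prony_design(t: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t)] + [np.exp(-t / tau) for tau in taus])


def fit_prony(
    sigma_pa: np.ndarray,
    t_s: np.ndarray,
    eps0: float,
    n_terms: int = 3,
    tau_starts: tuple[float, ...] = (1.0, 10.0, 100.0),
) -> RelaxationResult:
    """Constrained least-squares fit of a Prony series to σ(t) = ε₀·E(t).

    Variable projection: for a candidate set of time constants the moduli
    (E∞, Eᵢ) solve a non-negative least-squares problem; the time constants
    are optimised in log space with bounds, started from every multiset of
    ``tau_starts`` (log-spaced decades).  The best candidate by residual
    sum of squares wins; terms are returned sorted by ascending τ.
    """
    sigma = np.asarray(sigma_pa, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if eps0 <= 0:
        raise ValueError("eps0 must be positive")
    if sigma.size < 3 * n_terms + 1:
        raise ValueError(
            f"need at least {3 * n_terms + 1} samples for a {n_terms}-term fit"
        )
    y = sigma / eps0
    t0 = t - t[0]

    def amplitudes(log_tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = _prony_design(t0, np.exp(log_tau))
        c, _ = nnls(A, y)
        return c, A

    def residual(log_tau: np.ndarray) -> np.ndarray:
        c, A = amplitudes(log_tau)
        return A @ c - y

    best_rss = np.inf
    best_logtau = None
    log_bounds = (np.log(1e-3), np.log(1e4))
    for start in combinations_with_replacement(tau_starts, n_terms):
        try:
            sol = least_squares(
                residual,
                np.log(np.asarray(start)),
                bounds=log_bounds,
                method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        rss = float(2.0 * sol.cost)
        if rss < best_rss:
            best_rss = rss
            best_logtau = sol.x

    if best_logtau is None:
        raise PronyFitError("no Prony multi-start candidate converged")

    c, _ = amplitudes(best_logtau)
    taus = np.exp(best_logtau)
    e_inf = float(c[0])
    if e_inf <= 0:
        # degenerate data (e.g. stress decaying to ~0); keep a tiny floor so
        # the model object remains valid and report it via the residual
        e_inf = max(e_inf, 1e-12 * max(y.max(), 1.0))
    model = PronyModel(
        e_inf_pa=e_inf,
        terms=[(float(ci), float(taui)) for ci, taui in zip(c[1:], taus)],
    )
    if t[-1] - t[0] >= 100.0:
        reduction = relaxation_reduction(sigma, t)
    else:
        reduction = model.reduction_pct(100.0)
    return RelaxationResult(
        reduction_pct=float(np.clip(reduction, 0.0, 100.0)),
        prony=model,
        fit_rss=best_rss,
    )


def modulus_from_ramp(
    curve: StressStrainCurve, window: tuple[float, float] = (0.10, 0.15)
) -> float:
    """Elastic modulus from the stress–strain slope inside a strain window.

    Least-squares slope of σ versus ε restricted to ``window`` (default
    10–15% strain).  Raises if the curve does not span the window, which is
    how prematurely ruptured samples are flagged.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"strain window must have positive width, got {window}")
    if curve.eps.min() > lo or curve.eps.max() < hi:
        raise ValueError(
            f"curve spans [{curve.eps.min():.3f}, {curve.eps.max():.3f}], "
            f"does not cover the [{lo}, {hi}] window (premature rupture?)"
        )
    sel = (curve.eps >= lo) & (curve.eps <= hi)
    if sel.sum() < 2:
        raise ValueError("fewer than two samples inside the strain window")
    slope = np.polyfit(curve.eps[sel], curve.sigma_pa[sel], 1)[0]
    return float(slope)


class StressRelaxation:
    """Stress-relaxation analysis of one trace (model object).

    Built either from arrays (``t_s``, ``sigma_pa``) or from a labelled
    :class:`ForceTrace` via :meth:`from_trace`.  ``fit`` runs the
    constrained Prony fit and the 100 s reduction statistic.
    """

    def __init__(self, t_s: np.ndarray, sigma_pa: np.ndarray, eps0: float):
        self.t_s = np.asarray(t_s, dtype=float)
        self.sigma_pa = np.asarray(sigma_pa, dtype=float)
        self.eps0 = float(eps0)
        if self.t_s.shape != self.sigma_pa.shape:
            raise ValueError("t and sigma must have identical shape")

    @classmethod
    def from_trace(cls, trace: ForceTrace, eps0: float | None = None
                   ) -> "StressRelaxation":
        """Build from the relaxation segment of a labelled force trace.

        If ``eps0`` is not given it is computed from the (constant) indenter
        travel during relaxation via the arc-chord strain relation.
        """
        seg = trace.select("relaxation")
        curve = curve_from_trace(seg)
        if eps0 is None:
            eps0 = float(np.median(curve.eps))
        return cls(seg.t_s, curve.sigma_pa, eps0)

    def fit(self, n_terms: int = 3) -> "RelaxationResults":
        res = fit_prony(self.sigma_pa, self.t_s, self.eps0, n_terms=n_terms)
        return RelaxationResults(model=self, result=res)


@dataclass
class RelaxationResults:
    """Results wrapper around :class:`RelaxationResult` with reporting."""

    model: StressRelaxation
    result: RelaxationResult

    @property
    def prony(self) -> PronyModel:
        return self.result.prony

    @property
    def reduction_pct(self) -> float:
        return self.result.reduction_pct

    @property
    def fit_rss(self) -> float:
        return self.result.fit_rss

    def to_record(self) -> dict:
        p = self.prony
        return {
            "reduction_pct": self.reduction_pct,
            "prony": {
                "e_inf_MPa": p.e_inf_pa * 1e-6,
                "e_i_MPa": [e * 1e-6 for e, _ in p.terms],
                "tau_i_s": [tau for _, tau in p.terms],
            },
            "fit_rss": self.fit_rss,
        }

    def summary(self) -> str:
        p = self.prony
        lines = [
            "Stress-relaxation Prony fit",
            "===========================",
            f"applied strain eps0     : {self.model.eps0:8.4f}",
            f"stress reduction @100 s : {self.reduction_pct:8.2f} %",
            f"E_inf (long-term)       : {p.e_inf_pa * 1e-6:8.3f} MPa",
        ]
        for k, (e_i, tau_i) in enumerate(p.terms, start=1):
            lines.append(
                f"E_{k} = {e_i * 1e-6:6.3f} MPa   tau_{k} = {tau_i:8.2f} s"
            )
        lines.append(f"residual sum of squares : {self.fit_rss:10.3e}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data versus fitted σ(t) (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.t_s, m.sigma_pa * 1e-3, ".", ms=2, label="data")
        tt = np.linspace(m.t_s[0], m.t_s[-1], 400)
        ax.plot(tt, self.prony.stress(tt - m.t_s[0], m.eps0) * 1e-3,
                "-", label="Prony fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("stress (kPa)")
        ax.legend()
        return ax


class TensileRamp:
    """Ramp (rupture-test) analysis of one stress–strain curve."""

    def __init__(
        self,
        curve: StressStrainCurve,
        window: tuple[float, float] = (0.10, 0.15),
    ):
        self.curve = curve
        self.window = (float(window[0]), float(window[1]))

    @classmethod
    def from_trace(cls, trace: ForceTrace,
                   window: tuple[float, float] = (0.10, 0.15)) -> "TensileRamp":
        """Build from the ramp segment, truncating at rupture if detected."""
        seg = trace.select("ramp") if trace.segment is not None else trace
        cut = detect_rupture(seg)
        ruptured = cut is not None
        if ruptured:
            seg = ForceTrace(seg.t_s[:cut], seg.force_n[:cut],
                             seg.travel_um[:cut], seg.segment[:cut]
                             if seg.segment is not None else None, seg.geometry)
        obj = cls(curve_from_trace(seg), window)
        obj.ruptured = ruptured
        return obj

    ruptured: bool = False

    def fit(self) -> "RampResults":
        try:
            e = modulus_from_ramp(self.curve, self.window)
            premature = False
        except ValueError:
            if not self.ruptured:
                raise
            e = np.nan
            premature = True
        return RampResults(model=self, e_modulus_pa=e,
                           ruptured=self.ruptured, premature=premature)


@dataclass
class RampResults:
    """Window-slope modulus of a tensile ramp."""

    model: TensileRamp
    e_modulus_pa: float
    ruptured: bool = False
    premature: bool = False

    @property
    def e_modulus_kpa(self) -> float:
        return 1e-3 * self.e_modulus_pa

    def to_record(self) -> dict:
        return {
            "E_ext_kPa": self.e_modulus_kpa,
            "ruptured": bool(self.ruptured),
            "premature": bool(self.premature),
            "window": list(self.model.window),
        }

    def summary(self) -> str:
        lo, hi = self.model.window
        return "\n".join(
            [
                "Tensile ramp analysis",
                "=====================",
                f"strain window           : {100 * lo:.0f}-{100 * hi:.0f} %",
                f"window-slope modulus    : {self.e_modulus_kpa:8.2f} kPa",
                f"ruptured                : {self.ruptured}",
                f"premature (window unmet): {self.premature}",
            ]
        )
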