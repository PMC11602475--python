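"""Umbrella-sampling free energy, position-dependent diffusion, and the
inhomogeneous solubility-diffusion permeability coefficient.

The weighted histogram analysis method (WHAM) self-consistently unbiases
the window histograms:

    p(z) = sum_i n_i(z) / sum_i N_i exp((f_i - U_i(z)) / kT)
    f_i  = -kT ln sum_z p(z) exp(-U_i(z) / kT)

iterated until the window free energies f_i stop moving, then
dG(z) = -kT ln p(z), anchored to zero over the bulk-water plateau on the
starting side. The local diffusion coefficient comes from the force
autocorrelation method, D(z_i) = (RT)^2 / int_0^inf <dF(t) dF(0)> dt, and
the permeability from

    P = [ int exp(dG(z)/RT) / D(z) dz ]^-1

converted to cm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trajectory import WindowSeries
from .units import R_KJ, NM_PS_TO_CM_S


class PMFError(ValueError):
    """Bad window layout, non-convergence, or unusable profiles."""


# ---------------------------------------------------------------- schedule

@dataclass(frozen=True)
class WindowSchedule:
    centers: np.ndarray
    force_constant: float


def make_window_schedule(z_start: float = 4.0, z_end: float = -4.0,
                         spacing: float = 0.2,
                         force_constant: float = 100.0) -> WindowSchedule:
    """Evenly spaced umbrella windows from z_start toward z_end.

    Half-open count convention: centers are z_start, z_start -+ spacing,
    ..., excluding z_end itself, so the default 4.0 -> -4.0 nm span at
    0.2 nm spacing yields 40 windows.
    """
    if spacing <= 0:
        raise PMFError("spacing must be positive")
    span = z_end - z_start
    if span == 0:
        raise PMFError("zero-span schedule")
    n = int(round(abs(span) / spacing))
    if n == 0:
        raise PMFError("span smaller than spacing")
    step = math.copysign(spacing, span)
    centers = z_start + step * np.arange(n)
    return WindowSchedule(centers, force_constant)


def equilibration_trim(series: WindowSeries,
                       trim_fraction: float = 0.5) -> WindowSeries:
    """Drop the leading equilibration fraction of a window's samples."""
    if not 0.0 <= trim_fraction < 1.0:
        raise PMFError("trim fraction must be in [0, 1)")
    k = int(len(series.positions) * trim_fraction)
    if k >= len(series.positions):
        raise PMFError("trim would empty the window")
    return WindowSeries(series.window_center, series.force_constant,
                        series.times[k:], series.positions[k:],
                        None if series.forces is None else series.forces[k:])


# -------------------------------------------------------------------- WHAM

@dataclass
class PMFProfile:
    """Free-energy profile dG(z) in kJ/mol on a uniform z grid (nm),
    anchored to zero over the bulk plateau; unsampled bins are NaN and
    listed, never silently interpolated."""

    z: np.ndarray
    dG: np.ndarray
    uncertainty: np.ndarray
    anchor: str = "start-side bulk mean"
    unsampled: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def barrier_height(self, reference: str = "bulk") -> float:
        """Peak height over the bulk anchor ('bulk') or over the
        interfacial minimum ('minimum')."""
        finite = np.isfinite(self.dG)
        peak = np.nanmax(self.dG)
        if reference == "bulk":
            return float(peak)
        if reference == "minimum":
            return float(peak - np.nanmin(self.dG))
        raise PMFError(f"unknown reference {reference!r}")


def _logsumexp(a, axis=None):
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis) if axis is not None else float(out)


def wham(windows: list[WindowSeries], kT: float,
         bin_width: float = 0.05, tol: float = 1e-6,
         max_iter: int = 100_000, anchor_width: float = 0.5,
         min_overlap: int = 1) -> PMFProfile:
    """Self-consistent WHAM solution over the sampled range.

    Iterates the unbiased probabilities and window free energies until the
    max change in f_i drops below ``tol`` (kJ/mol). Adjacent windows must
    share at least ``min_overlap`` occupied bins, otherwise the gap is
    reported. The profile is anchored to zero over the outermost
    ``anchor_width`` nm of the sampled range on the side of the first
    window's center (the bulk phase the pull started from).
    """
    if not windows:
        raise PMFError("no windows")
    lo = min(w.positions.min() for w in windows)
    hi = max(w.positions.max() for w in windows)
    nbins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + np.arange(nbins + 1) * bin_width
    z = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(w.positions, bins=edges)[0]
                       for w in windows])                  # (W, B)
    order = np.argsort([w.window_center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        shared = np.sum((counts[a] > 0) & (counts[b] > 0))
        if shared < min_overlap:
            raise PMFError(
                "non-overlapping windows: gap between centers "
                f"{windows[a].window_center:g} and "
                f"{windows[b].window_center:g} nm")

    N = counts.sum(axis=1).astype(float)                   # (W,)
    bias = np.array([0.5 * w.force_constant * (z - w.window_center) ** 2
                     for w in windows])                    # (W, B) kJ/mol
    log_n_total = np.log(np.maximum(counts.sum(axis=0), 1e-300))
    sampled = counts.sum(axis=0) > 0

    f = np.zeros(len(windows))                             # kJ/mol
    logN = np.log(N)
    for _ in range(max_iter):
        # log denominator per bin: logsumexp_i [ln N_i + (f_i - U_i)/kT]
        denom = _logsumexp(logN[:, None] + (f[:, None] - bias) / kT, axis=0)
        logp = np.where(sampled, log_n_total - denom, -np.inf)
        # f_i = -kT ln sum_z p(z) exp(-U_i(z)/kT)
        f_new = -kT * _logsumexp(logp[None, :] - bias / kT, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise PMFError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {delta:.3g} kJ/mol)")

    dG = np.where(sampled, -kT * logp, np.nan)
    # anchor over the outermost anchor_width on the pull's starting side
    start = windows[0].window_center
    if abs(start - z[-1]) < abs(start - z[0]):
        bulk = z >= z[-1] - anchor_width
    else:
        bulk = z <= z[0] + anchor_width
    bulk &= sampled
    if not bulk.any():
        raise PMFError("no sampled bins in the bulk anchor region")
    dG -= np.nanmean(dG[bulk])
    with np.errstate(divide="ignore"):
        unc = np.where(sampled, kT / np.sqrt(np.maximum(
            counts.sum(axis=0), 1)), np.nan)
    return PMFProfile(z, dG, unc, unsampled=np.flatnonzero(~sampled))


# ----------------------------------------------- force-autocorrelation D(z)

@dataclass
class DiffusionProfile:
    z: np.ndarray
    D: np.ndarray            # nm^2/ps
    acf_integral: np.ndarray  # (kJ/mol/nm)^2 ps
    policy: str = "zero_crossing"


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    n = len(x)
    dx = x - x.mean()
    fft_len = 1 << (2 * n - 1).bit_length()
    X = np.fft.rfft(dx, fft_len)
    acf = np.fft.irfft(X * np.conj(X), fft_len)[:n]
    return acf / (n - np.arange(n))


def diffusion_from_force_autocorrelation(
        windows: list[WindowSeries], T: float,
        policy: str = "zero_crossing",
        max_lag_fraction: float = 0.1) -> DiffusionProfile:
    """Local diffusion coefficients from restraint-force fluctuations.

    D(z_i) = (RT)^2 / int_0^inf <dF(t) dF(0)> dt, with the integral
    truncated at the first zero crossing of the autocorrelation (default)
    or extended by an exponential tail fitted to the decay ('exp_tail').
    Series whose correlation is not resolved by the sampling interval
    (first zero crossing within 2 samples) are rejected as white-noise
    degenerate rather than silently integrated.
    """
    if policy not in ("zero_crossing", "exp_tail"):
        raise PMFError(f"unknown truncation policy {policy!r}")
    RT = R_KJ * T
    zs, Ds, integrals = [], [], []
    for w in windows:
        if w.forces is None:
            raise PMFError(f"window at {w.window_center:g} nm has no forces")
        dt = float(np.mean(np.diff(w.times)))
        acf = _autocorrelation(w.forces)
        acf = acf[: max(3, int(len(acf) * max_lag_fraction))]
        below = np.flatnonzero(acf <= 0)
        cut = below[0] if len(below) else len(acf)
        if cut <= 2:
            raise PMFError(
                f"window at {w.window_center:g} nm: force series is "
                "white-noise degenerate (unresolved correlation time)")
        integral = np.trapezoid(acf[:cut], dx=dt)
        if policy == "exp_tail":
            # fit ln acf over the resolved decay, integrate the tail
            k = max(3, cut // 2)
            y = np.log(acf[:k])
            t = np.arange(k) * dt
            slope, intercept = np.polyfit(t, y, 1)
            if slope < 0:
                tau = -1.0 / slope
                t_cut = cut * dt
                integral += math.exp(intercept) * tau * math.exp(-t_cut / tau)
        if integral <= 0:
            raise PMFError(
                f"window at {w.window_center:g} nm: non-positive "
                "autocorrelation integral")
        zs.append(w.window_center)
        Ds.append(RT ** 2 / integral)
        integrals.append(integral)
    return DiffusionProfile(np.asarray(zs), np.asarray(Ds),
                            np.asarray(integrals), policy)


# ------------------------------------------------------------ permeability

@dataclass
class PermeabilityResult:
    """Inhomogeneous solubility-diffusion permeability."""

    P: float                 # cm/s
    z: np.ndarray            # nm
    integrand: np.ndarray    # exp(dG/RT)/D, ps/nm^2
    T: float
    bounds: tuple[float, float]

    def recompute(self) -> float:
        """P from the stored integrand (reproducibility check)."""
        return 1.0 / np.trapezoid(self.integrand, self.z) * NM_PS_TO_CM_S


def permeability(pmf: PMFProfile, dprof: DiffusionProfile,
                 T: float = 298.0,
                 bounds: tuple[float, float] = (-4.0, 4.0)
                 ) -> PermeabilityResult:
    """P = 1 / int exp(dG(z)/RT) D(z)^-1 dz over the membrane span.

    The diffusion profile is interpolated onto the PMF grid; the PMF must
    be sampled (non-NaN) and D available over the whole integration range.
    """
    RT = R_KJ * T
    lo, hi = min(bounds), max(bounds)
    sel = (pmf.z >= lo) & (pmf.z <= hi)
    z = pmf.z[sel]
    dG = pmf.dG[sel]
    if len(z) < 2:
        raise PMFError("PMF grid does not cover the integration bounds")
    if np.any(~np.isfinite(dG)):
        raise PMFError("PMF has unsampled bins inside the bounds")
    dz_lo, dz_hi = dprof.z.min(), dprof.z.max()
    if dz_lo > z.min() or dz_hi < z.max():
        raise PMFError(
            f"diffusion profile spans [{dz_lo:g}, {dz_hi:g}] nm but the "
            f"PMF needs [{z.min():g}, {z.max():g}] nm")
    order = np.argsort(dprof.z)
    D = np.interp(z, dprof.z[order], dprof.D[order])
    if np.any(D <= 0):
        raise PMFError("non-positive D(z) inside the bounds")
    integrand = np.exp(dG / RT) / D
    P = 1.0 / np.trapezoid(integrand, z) * NM_PS_TO_CM_S
    return PermeabilityResult(P, z, integrand, T, (lo, hi))
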