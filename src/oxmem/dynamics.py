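"""Lateral lipid dynamics: drift-corrected tracks, mean-square
displacement, Einstein-relation diffusion coefficients, and the free-area
diagnostic.

The MSD is the time- and ensemble-averaged squared lateral displacement

    MSD(dt) = < |r_i(t + dt) - r_i(t)|^2 >_{i,t}

and D_lateral = slope / 4 over a fit window that avoids the short-time
and poor-statistics long-lag regimes. Before the MSD, tracks are
PBC-unwrapped and the whole-membrane center-of-mass motion is removed
first, then the residual per-leaflet (monolayer) motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory
from .units import NM2_PS_TO_UM2_S


class DynamicsError(ValueError):
    """Invalid tracks, lags, or fit window."""


@dataclass
class Tracks:
    """Drift-corrected, unwrapped 2-D COM tracks: (n_lipids, n_frames, 2)
    in nm, with per-lipid species and leaflet keys."""

    xy: np.ndarray
    times: np.ndarray
    species: np.ndarray
    leaflet: np.ndarray

    @property
    def n_lipids(self) -> int:
        return self.xy.shape[0]

    @property
    def n_frames(self) -> int:
        return self.xy.shape[1]


def unwrap_and_correct(traj: Trajectory, remove_membrane_com: bool = True,
                       remove_leaflet_com: bool = True) -> Tracks:
    """Per-lipid xy COM tracks, PBC-unwrapped, with whole-membrane and
    per-leaflet COM displacement removed (in that order).

    Each residue in the trajectory is one lipid; its COM is the
    mass-weighted mean of its atoms. Lipids must carry leaflet tags.
    """
    atoms = traj.atoms
    if "leaflet" not in atoms:
        raise DynamicsError("atoms need leaflet tags (assign_leaflets)")
    if (atoms["leaflet"] == "none").any() or atoms["leaflet"].isna().any():
        bad = atoms.loc[(atoms["leaflet"] == "none") |
                        atoms["leaflet"].isna(), "resid"].unique()
        raise DynamicsError(f"untagged lipids: residues {bad[:5].tolist()}")
    masses = atoms["mass"].to_numpy(float)
    resids = atoms["resid"].to_numpy()
    uniq, inverse = np.unique(resids, return_inverse=True)
    n_lip = len(uniq)

    # per-lipid COM per frame (wrapped); weight matrix is small enough
    w = np.zeros((n_lip, traj.n_atoms))
    w[inverse, np.arange(traj.n_atoms)] = masses
    w /= w.sum(axis=1, keepdims=True)
    com = np.einsum("ln,fnd->lfd", w, traj.coordinates[:, :, :2])

    # unwrap: shift each step to its minimum image
    box_xy = traj.boxes[:, :2]          # (F, 2)
    d = np.diff(com, axis=1)            # (L, F-1, 2)
    d -= np.round(d / box_xy[None, 1:, :]) * box_xy[None, 1:, :]
    xy = np.concatenate([com[:, :1, :],
                         com[:, :1, :] + np.cumsum(d, axis=1)], axis=1)

    species = np.array([atoms.loc[resids == r, "species"].iloc[0]
                        if "species" in atoms else "ALL" for r in uniq])
    leaflet = np.array([atoms.loc[resids == r, "leaflet"].iloc[0]
                        for r in uniq])
    lipid_mass = np.bincount(inverse, weights=masses)

    def remove_com(mask):
        drift = np.average(xy[mask], axis=0, weights=lipid_mass[mask])
        xy[mask] -= (drift - drift[0])[None, :, :]

    if remove_membrane_com:
        remove_com(np.ones(n_lip, bool))
    if remove_leaflet_com:
        for leaf in np.unique(leaflet):
            remove_com(leaflet == leaf)
    return Tracks(xy, traj.times, species, leaflet)


# ------------------------------------------------------------------- MSD

@dataclass
class MSDSeries:
    """Time- and ensemble-averaged lateral MSD per lag."""

    lags: np.ndarray       # ps
    msd: np.ndarray        # nm^2
    n_pairs: np.ndarray
    key: tuple = ("all", "all")
    per_lipid: np.ndarray | None = None  # (n_lipids, n_lags)

    def __post_init__(self):
        if self.msd[0] != 0.0 and self.lags[0] == 0.0:
            raise DynamicsError("MSD(0) must be 0")
        if np.any(self.msd < -1e-12):
            raise DynamicsError("negative MSD")
        if np.any(np.diff(self.lags) <= 0):
            raise DynamicsError("lags must increase")


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one coordinate series for all lags, O(n log n)."""
    n = len(x)
    fft_len = 1 << (2 * n - 1).bit_length()
    X = np.fft.rfft(x, fft_len)
    acf = np.fft.irfft(X * np.conj(X), fft_len)[:n]
    sq = x * x
    total = sq.sum()
    head = np.cumsum(sq)               # sum of the first k entries
    tail = np.cumsum(sq[::-1])         # sum of the last k entries
    k = np.arange(n)
    # S1(k) = sum over valid t of x_t^2 + x_{t+k}^2
    s1 = 2.0 * total - np.concatenate([[0.0], head[:-1]]) \
        - np.concatenate([[0.0], tail[:-1]])
    return s1 / (n - k) - 2.0 * acf / (n - k)


def msd_lateral(tracks: Tracks, max_lag: int | None = None,
                lags: np.ndarray | None = None,
                method: str = "fft") -> dict[tuple, MSDSeries]:
    """Sliding-window (time-averaged) lateral MSD per (species, leaflet).

    ``max_lag`` defaults to n_frames // 5; an explicit integer ``lags``
    array (in frames) may subsample. ``method`` 'fft' and 'naive' agree to
    floating-point precision; naive is O(n^2) and intended for validation.
    """
    n = tracks.n_frames
    if n < 2:
        raise DynamicsError("need at least 2 frames")
    if max_lag is None:
        max_lag = max(1, n // 5)
    if lags is None:
        lags = np.arange(max_lag + 1)
    lags = np.asarray(lags, int)
    if lags.max() >= n:
        keep = lags < n
        lags = lags[keep]

    per_lipid = np.empty((tracks.n_lipids, len(lags)))
    for i in range(tracks.n_lipids):
        if method == "fft":
            full = (_msd_fft_1d(tracks.xy[i, :, 0])
                    + _msd_fft_1d(tracks.xy[i, :, 1]))
            per_lipid[i] = full[lags]
        elif method == "naive":
            for j, k in enumerate(lags):
                if k == 0:
                    per_lipid[i, j] = 0.0
                else:
                    d = tracks.xy[i, k:] - tracks.xy[i, :-k]
                    per_lipid[i, j] = np.mean(np.sum(d * d, axis=1))
        else:
            raise DynamicsError(f"unknown method {method!r}")
    per_lipid[:, lags == 0] = 0.0

    dt = tracks.times[1] - tracks.times[0]
    out = {}
    keys = list(zip(tracks.species, tracks.leaflet))
    for key in sorted(set(keys)):
        mask = np.array([k == key for k in keys])
        out[key] = MSDSeries(
            lags * dt, per_lipid[mask].mean(axis=0),
            n_pairs=(n - lags) * mask.sum(),
            key=key, per_lipid=per_lipid[mask])
    out[("all", "all")] = MSDSeries(
        lags * dt, per_lipid.mean(axis=0), n_pairs=(n - lags) * len(keys),
        key=("all", "all"), per_lipid=per_lipid)
    return out


# -------------------------------------------------------------- diffusion

@dataclass
class DiffusionEstimate:
    """Einstein-relation diffusion coefficient in um^2/s."""

    D: float
    fit_window: tuple[float, float]  # ps
    r_squared: float
    stderr: float
    per_lipid_D: np.ndarray | None = None  # um^2/s
    negative: bool = False

    @property
    def D_mean_sd(self) -> tuple[float, float]:
        """Mean +/- SD over per-lipid fits (equal weight per lipid)."""
        if self.per_lipid_D is None:
            return self.D, math.nan
        return (float(self.per_lipid_D.mean()),
                float(self.per_lipid_D.std(ddof=1)))


def diffusion_coefficient(msd: MSDSeries,
                          fit_window: tuple[float, float] = (0.1, 0.5),
                          window_in_ps: bool = False) -> DiffusionEstimate:
    """Least-squares MSD slope over the fit window, divided by 4.

    ``fit_window`` is a fraction of the maximum lag by default (10-50%),
    or absolute ps bounds with ``window_in_ps``. Negative estimates are
    reported and flagged, never clipped. Per-lipid estimates (when the
    series carries per-lipid MSDs) give the mean +/- SD across lipids.
    """
    lags = msd.lags
    if window_in_ps:
        lo, hi = fit_window
    else:
        lo, hi = (f * lags.max() for f in fit_window)
    sel = (lags >= lo) & (lags <= hi) & (lags > 0)
    if sel.sum() < 5:
        raise DynamicsError(
            f"fit window [{lo:g}, {hi:g}] ps contains {int(sel.sum())} "
            "lags; need >= 5")
    x, y = lags[sel], msd.msd[sel]

    def fit(yv):
        A = np.vstack([x, np.ones_like(x)]).T
        coef, res, *_ = np.linalg.lstsq(A, yv, rcond=None)
        slope = coef[0]
        pred = A @ coef
        ss_res = float(np.sum((yv - pred) ** 2))
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = max(len(x) - 2, 1)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = math.sqrt(ss_res / dof / sxx) if sxx > 0 else math.nan
        return slope, r2, se

    slope, r2, se = fit(y)
    D_nm = slope / 4.0
    per = None
    if msd.per_lipid is not None and len(msd.per_lipid) > 1:
        per = np.array([fit(m[sel])[0] / 4.0 * NM2_PS_TO_UM2_S
                        for m in msd.per_lipid])
    return DiffusionEstimate(
        D=D_nm * NM2_PS_TO_UM2_S, fit_window=(float(lo), float(hi)),
        r_squared=r2, stderr=se / 4.0 * NM2_PS_TO_UM2_S,
        per_lipid_D=per, negative=bool(D_nm < 0))


@dataclass(frozen=True)
class FreeAreaInputs:
    """Free-area-theory inputs: cross-sectional area per lipid a_l and
    free area per molecule a_f, both nm^2."""

    a_l: float
    a_f: float

    def __post_init__(self):
        if self.a_l <= 0 or self.a_f <= 0:
            raise DynamicsError("areas must be positive")


def free_area_relative_D(inputs: FreeAreaInputs,
                         reference: FreeAreaInputs) -> float:
    """Free-area-theory diffusion ratio exp(-a_l/a_f) / exp(-a_l'/a_f').

    Diagnostic only: relates lateral mobility to lipid packing."""
    return math.exp(reference.a_l / reference.a_f - inputs.a_l / inputs.a_f)
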