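"""Synthetic-data generators with attached ground truth.

Every downstream analysis stage can be validated without MD runs: the
generators here emulate (a) 2-D Brownian lipid center-of-mass motion with
species-specific diffusion constants and optional per-leaflet drift,
(b) tilted all-trans acyl chains for order-parameter and tilt-angle
analytics, (c) Gaussian-layered bilayers for density/thickness recovery,
(d) exact biased Boltzmann samples from a known free-energy profile under
harmonic umbrella biases, (e) stationary Ornstein-Uhlenbeck force series
whose autocorrelation integral encodes a known local diffusion constant,
and (f) hydrogen-bond fixtures with a planted number of bonds.

The generators target statistical structure, not mechanics: there are no
inter-lipid forces, so passing tests demonstrate estimator correctness,
not force-field realism. Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np
import pandas as pd

from .units import R_KJ, UM2_S_TO_NM2_PS
from .trajectory import Frame, Trajectory, WindowSeries


class SyntheticError(ValueError):
    """Invalid generator parameters."""


@dataclass
class SyntheticTruth:
    """Ground-truth parameters attached to every generated dataset."""

    seed: int
    D_by_species: dict[str, float] | None = None          # um^2/s
    leaflet_drift: dict[str, tuple[float, float]] | None = None  # nm/ps
    pmf_grid: np.ndarray | None = None                    # nm
    pmf_values: np.ndarray | None = None                  # kJ/mol
    biased_densities: list[tuple[np.ndarray, np.ndarray]] | None = None
    D_of_z: np.ndarray | None = None                      # nm^2/ps
    imposed_tilts: np.ndarray | None = None               # degrees
    layer_params: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x
        return json.dumps({k: conv(v) for k, v in self.__dict__.items()})


# ------------------------------------------------------ Brownian membrane

def gen_brownian_membrane(comp, D_by_species: dict[str, float],
                          n_frames: int, dt: float,
                          box=(15.0, 15.0, 8.0),
                          leaflet_drift: dict | None = None,
                          seed: int = 0):
    """2-D Brownian walks of lipid COM markers, one marker per lipid.

    ``D_by_species`` is in um^2/s; per-step displacement per axis is
    N(0, 2 D dt) plus the shared per-leaflet drift (nm/ps). z stays fixed
    per leaflet; coordinates are wrapped into the box. Returns
    (Trajectory, SyntheticTruth); the truth carries the unwrapped tracks.
    """
    if n_frames < 2:
        raise SyntheticError("need at least 2 frames")
    if dt <= 0:
        raise SyntheticError("dt must be positive")
    for sp, D in D_by_species.items():
        if D < 0:
            raise SyntheticError(f"negative diffusion constant for {sp}")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    drift = {"inner": np.zeros(2), "outer": np.zeros(2)}
    if leaflet_drift:
        for leaf, v in leaflet_drift.items():
            drift[leaf] = np.asarray(v, float)

    species, leaflets = [], []
    for leaf in comp.leaflets:
        for sp, n in comp.leaflets[leaf]:
            if sp.name not in D_by_species:
                raise SyntheticError(f"no diffusion constant for {sp.name}")
            species += [sp.name] * n
            leaflets += [leaf] * n
    n_lipids = len(species)
    D_nm = np.array([D_by_species[s] * UM2_S_TO_NM2_PS for s in species])
    sigma = np.sqrt(2.0 * D_nm * dt)

    start = np.empty((n_lipids, 3))
    start[:, 0] = rng.uniform(0, box[0], n_lipids)
    start[:, 1] = rng.uniform(0, box[1], n_lipids)
    start[:, 2] = np.where(np.asarray(leaflets) == "outer",
                           box[2] / 2 + 1.0, box[2] / 2 - 1.0)
    steps = rng.normal(size=(n_frames - 1, n_lipids, 2)) * sigma[None, :, None]
    for leaf in ("inner", "outer"):
        mask = np.asarray(leaflets) == leaf
        steps[:, mask, :] += drift[leaf][None, None, :] * dt
    tracks = np.concatenate([np.zeros((1, n_lipids, 2)),
                             np.cumsum(steps, axis=0)]) + start[None, :, :2]
    coords = np.empty((n_frames, n_lipids, 3))
    coords[:, :, :2] = np.mod(tracks, box[:2][None, None, :])
    coords[:, :, 2] = start[:, 2][None, :]

    atoms = pd.DataFrame({
        "resid": np.arange(1, n_lipids + 1),
        "resname": [s[:4] for s in species],
        "name": ["COM"] * n_lipids,
        "mass": np.ones(n_lipids),
        "species": species,
        "leaflet": leaflets,
    })
    traj = Trajectory(coords, np.tile(box, (n_frames, 1)),
                      np.arange(n_frames) * dt, atoms)
    truth = SyntheticTruth(
        seed=seed, D_by_species=dict(D_by_species),
        leaflet_drift={k: tuple(v) for k, v in drift.items()},
        extras={"dt": dt, "unwrapped_tracks": tracks})
    return traj, truth


# -------------------------------------------------------- ordered chains

def gen_ordered_chains(n_chains: int, carbon_count: int,
                       tilt_deg: float | str = 0.0,
                       gauche_fraction: float = 0.0,
                       seed: int = 0,
                       leaflet: str = "outer",
                       head_marker: bool = True):
    """All-trans carbon skeletons tilted about a random azimuth.

    ``tilt_deg`` is a fixed tilt (degrees from the leaflet inward normal)
    or the string 'isotropic' for uniformly random chain orientations on
    the sphere. With gauche_fraction=0 and tilt t, every internal
    C(j-1)->C(j+1) skeletal axis makes exactly angle t with the normal, so
    the expected deuterium order parameter is (3 cos^2 t - 1)/2 at every
    internal carbon. Nonzero ``gauche_fraction`` kinks the running axis by
    60 degrees at randomly chosen carbons.

    Returns (Frame, atoms, SyntheticTruth). Chains hang from z = +2 nm
    (outer leaflet, inward = -z) or z = -2 nm (inner, inward = +z).
    """
    if isinstance(tilt_deg, str):
        if tilt_deg != "isotropic":
            raise SyntheticError(f"unknown tilt spec {tilt_deg!r}")
    elif not 0.0 <= tilt_deg <= 90.0:
        raise SyntheticError("tilt must be in [0, 90] degrees")
    rng = np.random.default_rng(seed)
    d = 0.127  # C-C projection on the chain axis, nm (all-trans)
    h = 0.042  # zigzag half-amplitude, nm
    inward = np.array([0.0, 0.0, -1.0 if leaflet == "outer" else 1.0])
    z0 = 2.0 if leaflet == "outer" else -2.0
    spacing = 1.0

    coords, records, tilts = [], [], []
    ncols = math.ceil(math.sqrt(n_chains))
    for c in range(n_chains):
        if tilt_deg == "isotropic":
            u = _random_unit(rng)
            tilt = math.degrees(math.acos(np.clip(np.dot(u, inward), -1, 1)))
        else:
            phi = rng.uniform(0, 2 * np.pi)
            tilt = float(tilt_deg)
            u = _tilted_axis(inward, math.radians(tilt), phi)
        tilts.append(tilt)
        w = _perpendicular(u, rng)
        gx, gy = divmod(c, ncols)
        origin = np.array([gx * spacing, gy * spacing, z0])
        pos = origin.copy()
        axis = u.copy()
        pts = [origin + h * w]
        for j in range(1, carbon_count):
            if gauche_fraction > 0 and rng.random() < gauche_fraction:
                axis = _kink(axis, w, rng)
            pos = pos + d * axis
            pts.append(pos + ((-1) ** j) * h * w)
        if head_marker:
            records.append((c + 1, "CHN", "P", 31.0, "CHN", leaflet))
            coords.append(pts[0] - d * u)
        for j, p in enumerate(pts, 1):
            records.append((c + 1, "CHN", f"C{j}", 12.0, "CHN", leaflet))
            coords.append(p)
    coords = np.asarray(coords)
    span = max(ncols * spacing, 1.0)
    frame = Frame(coords, np.array([span + 2, span + 2, 10.0]), 0.0)
    atoms = pd.DataFrame(records, columns=[
        "resid", "resname", "name", "mass", "species", "leaflet"])
    expected = None
    if not isinstance(tilt_deg, str) and gauche_fraction == 0:
        ct = math.cos(math.radians(tilt_deg))
        expected = 0.5 * (3 * ct * ct - 1)
    truth = SyntheticTruth(seed=seed, imposed_tilts=np.asarray(tilts),
                           extras={"expected_scd": expected,
                                   "gauche_fraction": gauche_fraction})
    return frame, atoms, truth


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular(u, rng):
    v = rng.normal(size=3)
    v -= np.dot(v, u) * u
    n = np.linalg.norm(v)
    if n < 1e-12:
        return _perpendicular(u, rng)
    return v / n


def _tilted_axis(inward, theta, phi):
    # orthonormal frame around the inward normal
    a = np.array([1.0, 0.0, 0.0])
    e1 = a - np.dot(a, inward) * inward
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(inward, e1)
    return (math.cos(theta) * inward
            + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2))


def _kink(axis, w, rng):
    # rotate the running axis by 60 degrees about a random perpendicular
    k = _perpendicular(axis, rng)
    ang = math.radians(60.0) * rng.choice([-1.0, 1.0])
    return (axis * math.cos(ang) + np.cross(k, axis) * math.sin(ang)
            + k * np.dot(k, axis) * (1 - math.cos(ang)))


# -------------------------------------------------------- layered bilayer

def gen_layered_bilayer(layer_params: dict, n_frames: int,
                        n_waters: int = 0,
                        water_exclusion_halfwidth: float = 2.8,
                        box=(8.0, 8.0, 9.0), seed: int = 0):
    """Gaussian-layered bilayer test bed for density-profile analysis.

    ``layer_params`` maps a component name to a dict with keys z_mean (nm,
    the magnitude; layers are mirrored about z=0), sigma (nm),
    n_per_leaflet and mass (amu). Waters (mass 18, name W) are uniform in
    the box outside the exclusion slab |z| < halfwidth. z coordinates are
    reported relative to the membrane center; the box is centered so that
    z=0 maps to box_z/2 when wrapped coordinates are required downstream.
    """
    for name, p in layer_params.items():
        if p["sigma"] <= 0:
            raise SyntheticError(f"sigma for {name} must be positive")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)

    records = []
    resid = 0
    sizes = []
    for name, p in layer_params.items():
        for leaf, sign in (("inner", -1.0), ("outer", 1.0)):
            for _ in range(p["n_per_leaflet"]):
                resid += 1
                records.append((resid, name[:4], name[:4], p["mass"],
                                name, leaf))
        sizes.append((name, p))
    for _ in range(n_waters):
        resid += 1
        records.append((resid, "W", "W", 18.0, "water", "none"))
    atoms = pd.DataFrame(records, columns=[
        "resid", "resname", "name", "mass", "species", "leaflet"])

    n_atoms = len(atoms)
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :, 0] = rng.uniform(0, box[0], (n_frames, n_atoms))
    coords[:, :, 1] = rng.uniform(0, box[1], (n_frames, n_atoms))
    i = 0
    for name, p in sizes:
        for sign in (-1.0, 1.0):
            n = p["n_per_leaflet"]
            coords[:, i:i + n, 2] = rng.normal(
                sign * p["z_mean"], p["sigma"], (n_frames, n))
            i += n
    if n_waters:
        hw = water_exclusion_halfwidth
        avail = box[2] / 2 - hw
        if avail <= 0:
            raise SyntheticError("exclusion slab wider than the box")
        u = rng.uniform(-avail, avail, (n_frames, n_waters))
        coords[:, i:, 2] = np.where(u >= 0, u + hw, u - hw)
    traj = Trajectory(coords, np.tile(box, (n_frames, 1)),
                      np.arange(n_frames, dtype=float), atoms)
    truth = SyntheticTruth(
        seed=seed,
        layer_params={k: dict(v) for k, v in layer_params.items()},
        extras={"n_waters": n_waters,
                "water_exclusion_halfwidth": water_exclusion_halfwidth})
    return traj, truth


# -------------------------------------------------------- umbrella samples

def gen_umbrella_samples(pmf_true, window_centers, force_constant: float,
                         n_per_window: int, kT: float, seed: int = 0,
                         grid_points: int = 10_000,
                         span: tuple[float, float] | None = None):
    """Exact biased Boltzmann samples per umbrella window.

    ``pmf_true`` is a callable G(z) in kJ/mol. Samples are drawn by
    inverse-CDF on a fine grid (rejection-free and reproducible) from
    density ~ exp(-[G(z) + k/2 (z - z_i)^2] / kT). The exact biased
    density per window is retained in the truth for oracle comparisons.
    With k=0 a bounded ``span`` must be given.
    """
    if force_constant < 0:
        raise SyntheticError("force constant must be >= 0")
    if force_constant == 0 and span is None:
        raise SyntheticError("unbiased windows need an explicit span")
    rng = np.random.default_rng(seed)
    windows, densities = [], []
    for c in window_centers:
        if force_constant > 0:
            half = 6.0 * math.sqrt(kT / force_constant) + 0.5
            lo, hi = c - half, c + half
            if span is not None:
                lo, hi = max(lo, span[0]), min(hi, span[1])
        else:
            lo, hi = span
        grid = np.linspace(lo, hi, grid_points)
        energy = np.asarray(pmf_true(grid), float) \
            + 0.5 * force_constant * (grid - c) ** 2
        if not np.all(np.isfinite(energy)):
            raise SyntheticError("PMF not finite on sampling range")
        logp = -energy / kT
        logp -= logp.max()
        pdf = np.exp(logp)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
        pdf /= cdf[-1]
        cdf /= cdf[-1]
        samples = np.interp(rng.uniform(0, 1, n_per_window), cdf, grid)
        windows.append(WindowSeries(float(c), force_constant,
                                    np.arange(n_per_window, dtype=float),
                                    samples))
        densities.append((grid, pdf))
    zg = np.linspace(min(float(c) for c in window_centers) - 1.0,
                     max(float(c) for c in window_centers) + 1.0, 2001)
    truth = SyntheticTruth(seed=seed, pmf_grid=zg,
                           pmf_values=np.asarray(pmf_true(zg), float),
                           biased_densities=densities,
                           extras={"kT": kT, "force_constant": force_constant})
    return windows, truth


# ----------------------------------------------------------- force series

def gen_force_series(D_target, T: float, tau: float, n: int, dt: float,
                     seed: int = 0, centers=None):
    """Stationary Ornstein-Uhlenbeck force series per window.

    Autocovariance sigma^2 exp(-t/tau) with sigma^2 tau = (RT)^2 / D, so
    the force-autocorrelation integral estimator should recover D_target
    (nm^2/ps). ``D_target`` may be a scalar or one value per window.
    """
    if tau <= 0:
        raise SyntheticError("correlation time must be positive")
    if tau < 3.0 * dt:
        raise SyntheticError(
            f"under-resolved: tau={tau} ps must be >= 3*dt ({3 * dt} ps)")
    D = np.atleast_1d(np.asarray(D_target, float))
    if np.any(D <= 0):
        raise SyntheticError("D_target must be positive")
    if centers is not None:
        centers = np.asarray(centers, float)
        if len(D) == 1:
            D = np.full(len(centers), D[0])
        elif len(D) != len(centers):
            raise SyntheticError(
                f"{len(D)} diffusion targets for {len(centers)} windows")
    rng = np.random.default_rng(seed)
    RT = R_KJ * T
    rho = math.exp(-dt / tau)
    series = []
    from scipy.signal import lfilter
    for Di in D:
        sigma2 = RT ** 2 / (Di * tau)
        x0 = rng.normal(0.0, math.sqrt(sigma2))
        innov = rng.normal(0.0, math.sqrt(sigma2 * (1 - rho * rho)), n - 1)
        rest, _ = lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
        series.append(np.concatenate([[x0], rest]))
    if centers is None:
        centers = np.arange(len(D), dtype=float)
    windows = [WindowSeries(float(c), 0.0, np.arange(n) * dt,
                            np.zeros(n), forces=s)
               for c, s in zip(centers, series)]
    truth = SyntheticTruth(seed=seed, D_of_z=D,
                           extras={"tau": tau, "T": T, "dt": dt,
                                   "sigma2": (RT ** 2 / (D * tau)).tolist()})
    return windows, truth


# ----------------------------------------------------------- hbond fixture

def gen_hbond_fixture(k_bonds: int, k_nonbonds: int,
                      dist_margin: float = 0.05,
                      angle_margin: float = 10.0,
                      max_da: float = 0.35, max_angle: float = 30.0,
                      box=(20.0, 20.0, 20.0), seed: int = 0):
    """Frame with exactly ``k_bonds`` donor-H-acceptor triplets satisfying
    the geometric criteria and ``k_nonbonds`` violating them by the given
    margins (alternating distance and angle violations).

    Returns (Frame, donors, acceptors, atoms) where donors is a list of
    (D_index, H_index) pairs and acceptors an index array.
    """
    if dist_margin <= 0 or angle_margin <= 0:
        raise SyntheticError("margins must be positive (ambiguous fixture)")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    total = k_bonds + k_nonbonds
    coords, donors, acceptors, records = [], [], [], []
    ncols = max(1, math.ceil(total ** (1 / 3)))
    pitch = min(box) / max(ncols, 1)
    if pitch < 2.5 * max_da and total > 0:
        raise SyntheticError("box too small to separate fixture triplets")
    idx = 0
    for t in range(total):
        gx, r = divmod(t, ncols * ncols)
        gy, gz = divmod(r, ncols)
        origin = (np.array([gx, gy, gz]) + 0.5) * pitch
        direction = _random_unit(rng)
        if t < k_bonds:
            dda = max_da - dist_margin
            theta = max(max_angle - angle_margin, 0.0)
        elif (t - k_bonds) % 2 == 0:
            dda = max_da + dist_margin
            theta = 5.0
        else:
            dda = max_da - dist_margin
            theta = max_angle + angle_margin
        D = origin
        A = origin + dda * direction
        perp = _perpendicular(direction, rng)
        hdir = (math.cos(math.radians(theta)) * direction
                + math.sin(math.radians(theta)) * perp)
        H = D + 0.1 * hdir
        for p, name in ((D, "OD"), (H, "HD"), (A, "OA")):
            coords.append(np.mod(p, box))
            records.append((t + 1, "FIX", name, 16.0 if name != "HD" else 1.0,
                            "fixture", "none"))
        donors.append((idx, idx + 1))
        acceptors.append(idx + 2)
        idx += 3
    frame = Frame(np.asarray(coords).reshape(-1, 3) if coords
                  else np.zeros((0, 3)), box, 0.0)
    atoms = pd.DataFrame(records, columns=[
        "resid", "resname", "name", "mass", "species", "leaflet"])
    return frame, donors, np.asarray(acceptors, int), atoms
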