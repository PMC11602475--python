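"""Static structural observables of bilayer trajectories.

Mass density profiles along the bilayer normal (recentered on the membrane
center of mass), water-zone occupancy, phosphate-peak membrane thickness,
area per lipid, the skeletal-vector deuterium order parameter

    S_CD(j) = < (3 cos^2 theta_j - 1) / 2 >

with theta_j the angle between the C(j-1)->C(j+1) axis and the membrane
normal (z), and the nine-angle tail-geometry scheme (alpha tilt angles,
the sn-1/sn-2 splay beta, interior bend angles gamma at a pivot carbon,
and segment tilt angles delta). Alpha and delta are measured against the
per-leaflet inward normal so that 0 degrees means "pointing into the
bilayer core" in both leaflets; gamma uses the interior-angle convention
(a straight chain reads 180 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory, Frame
from .units import AMU_PER_NM3_TO_KG_M3


class StructureError(ValueError):
    """Invalid selection or unresolvable structural feature."""


# ---------------------------------------------------------------- density

@dataclass
class DensityProfile:
    """Per-component mass density (kg/m^3) vs distance from the membrane
    center (nm). Bins are uniform; z=0 is the membrane center of mass."""

    bin_centers: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float
    n_frames: int = 1

    def component(self, name: str) -> np.ndarray:
        if name not in self.densities:
            raise StructureError(f"profile has no component {name!r}")
        return self.densities[name]


def _resolve_selection(atoms: pd.DataFrame, sel) -> np.ndarray:
    """Selections are boolean masks, index arrays, or species names."""
    if isinstance(sel, str):
        mask = (atoms.get("species", atoms["resname"]) == sel).to_numpy()
    else:
        sel = np.asarray(sel)
        if sel.dtype == bool:
            mask = sel
        else:
            mask = np.zeros(len(atoms), bool)
            mask[sel] = True
    if not mask.any():
        raise StructureError(f"empty selection {sel!r}")
    return mask


def mass_density_profile(traj: Trajectory, selections: dict,
                         bin_width: float = 0.05,
                         center_selection=None) -> DensityProfile:
    """Frame-averaged mass density per component vs z from the membrane COM.

    ``selections`` maps component names to selections (species name,
    boolean mask, or index array). The profile is recentered each frame on
    the mass-weighted center of ``center_selection`` (default: every atom
    in the union of the selections).
    """
    if bin_width <= 0:
        raise StructureError("bin width must be positive")
    masks = {name: _resolve_selection(traj.atoms, sel)
             for name, sel in selections.items()}
    union = np.any(list(masks.values()), axis=0)
    cmask = union if center_selection is None else \
        _resolve_selection(traj.atoms, center_selection)
    masses = traj.atoms["mass"].to_numpy(float)

    half = traj.boxes[:, 2].max() / 2.0
    nbins = int(np.ceil(2 * half / bin_width))
    edges = (np.arange(nbins + 1) - nbins / 2.0) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    hists = {name: np.zeros(nbins) for name in masks}
    for f in range(traj.n_frames):
        z = traj.coordinates[f, :, 2]
        zc = np.average(z[cmask], weights=masses[cmask])
        area = traj.boxes[f, 0] * traj.boxes[f, 1]
        dz = z - zc
        for name, mask in masks.items():
            h, _ = np.histogram(dz[mask], bins=edges, weights=masses[mask])
            hists[name] += h / (bin_width * area)
    densities = {name: h / traj.n_frames * AMU_PER_NM3_TO_KG_M3
                 for name, h in hists.items()}
    return DensityProfile(centers, densities, bin_width, traj.n_frames)


def water_zone_counts(traj: Trajectory, water_selection,
                      zone_width: float = 0.4, n_zones: int = 6,
                      center_selection=None) -> pd.DataFrame:
    """Time series of water counts in symmetric slabs about the membrane
    center: zone i collects |z - z_center| in [(i-1) w, i w)."""
    if zone_width <= 0:
        raise StructureError("zone width must be positive")
    wmask = _resolve_selection(traj.atoms, water_selection)
    if center_selection is None:
        cmask = ~wmask
        if not cmask.any():
            raise StructureError("no membrane atoms to center on")
    else:
        cmask = _resolve_selection(traj.atoms, center_selection)
    masses = traj.atoms["mass"].to_numpy(float)
    counts = np.zeros((traj.n_frames, n_zones), int)
    for f in range(traj.n_frames):
        z = traj.coordinates[f, :, 2]
        zc = np.average(z[cmask], weights=masses[cmask])
        dz = np.abs(z[wmask] - zc)
        zone = np.floor(dz / zone_width).astype(int)
        inside = zone < n_zones
        counts[f] = np.bincount(zone[inside], minlength=n_zones)
    return pd.DataFrame(counts, index=traj.times,
                        columns=[f"zone{i + 1}" for i in range(n_zones)])


# -------------------------------------------------------------- thickness

@dataclass
class ThicknessResult:
    peak_inner: float   # nm, < 0
    peak_outer: float   # nm, > 0
    thickness: float    # nm, peak-to-peak
    leaflet_thickness: dict[str, float] = field(default_factory=dict)


def _smooth3(y: np.ndarray) -> np.ndarray:
    pad = np.pad(y, 1, mode="edge")
    return (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0


def _parabolic_peak(z: np.ndarray, y: np.ndarray) -> float:
    """Sub-bin peak position from a 3-point parabolic fit around argmax."""
    if len(y) < 3:
        raise StructureError("profile half too short for peak localization")
    if y.max() <= 0 or y.max() < 2.0 * y.mean():
        raise StructureError("no resolvable peak above the noise floor")
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(z[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(z[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(z[i] + shift * (z[1] - z[0]))


def _leaflet_peaks(profile: DensityProfile, component: str):
    y = _smooth3(profile.component(component))
    z = profile.bin_centers
    lo, hi = z < 0, z > 0
    try:
        p_in = _parabolic_peak(z[lo], y[lo])
        p_out = _parabolic_peak(z[hi], y[hi])
    except StructureError as exc:
        raise StructureError(
            f"component {component!r}: {exc} (one dominant peak per "
            "leaflet required)")
    return p_in, p_out


def membrane_thickness(profile: DensityProfile,
                       component: str = "phosphate") -> ThicknessResult:
    """Peak-to-peak distance of the (smoothed, parabolic-refined) head-
    group density maxima in each half-space."""
    p_in, p_out = _leaflet_peaks(profile, component)
    return ThicknessResult(
        peak_inner=p_in, peak_outer=p_out, thickness=p_out - p_in,
        leaflet_thickness={"inner": -p_in, "outer": p_out})


def profile_peak_shift(profile_a: DensityProfile, profile_b: DensityProfile,
                       component: str) -> dict[str, float]:
    """Signed per-leaflet peak displacement of B relative to A; positive
    means B's peak moved toward the membrane center."""
    a_in, a_out = _leaflet_peaks(profile_a, component)
    b_in, b_out = _leaflet_peaks(profile_b, component)
    return {"inner": -(abs(b_in) - abs(a_in)),
            "outer": -(abs(b_out) - abs(a_out))}


# ---------------------------------------------------------- area per lipid

def area_per_lipid(traj: Trajectory, leaflet: str,
                   include_cholesterol: bool = False):
    """Lateral box area / leaflet lipid count, per frame and averaged.

    Lipid counts come from the trajectory's atom metadata (one residue per
    lipid); cholesterol (species CHOL) is excluded unless requested.
    """
    atoms = traj.atoms
    if "leaflet" not in atoms or "species" not in atoms:
        raise StructureError("atoms need species and leaflet tags")
    sub = atoms[atoms["leaflet"] == leaflet]
    if not include_cholesterol:
        sub = sub[sub["species"] != "CHOL"]
    n = sub["resid"].nunique()
    if n == 0:
        raise StructureError(f"no lipids in leaflet {leaflet!r}")
    series = traj.boxes[:, 0] * traj.boxes[:, 1] / n
    return series, float(series.mean())


# ---------------------------------------------------------- order parameter

@dataclass
class OrderParameterProfile:
    """Per-carbon skeletal S_CD with SD and sample counts, per chain key."""

    table: pd.DataFrame  # columns: chain, carbon, scd, sd, n

    def per_chain_average(self, include_first_internal: bool = True
                          ) -> pd.DataFrame:
        """Chain-averaged S_CD (mean over internal carbons, with or
        without the carbon adjacent to the carbonyl)."""
        t = self.table
        if not include_first_internal:
            first = t.groupby("chain")["carbon"].transform("min")
            t = t[t["carbon"] > first]
        return t.groupby("chain", as_index=False).agg(
            scd=("scd", "mean"), sd=("sd", "mean"))


def chain_indices_from_atoms(atoms: pd.DataFrame,
                             group_by: str = "resid",
                             chain_key: str = "species") -> dict:
    """Build ordered carbon index lists (C1..Cn) per chain copy, grouped
    under a chain identity key, from C-numbered atom names."""
    chains: dict[str, list[np.ndarray]] = {}
    carbon = atoms["name"].str.fullmatch(r"C\d+")
    sub = atoms[carbon.fillna(False)]
    for (_, grp) in sub.groupby(group_by):
        order = grp["name"].str.lstrip("C").astype(int).argsort()
        idx = grp.index.to_numpy()[order.to_numpy()]
        key = str(grp[chain_key].iloc[0])
        chains.setdefault(key, []).append(idx)
    return chains


def deuterium_order_parameter(traj_or_frame, chains: dict
                              ) -> OrderParameterProfile:
    """Skeletal-vector deuterium order parameter per internal carbon.

    ``chains`` maps a chain identity key to a list of ordered carbon
    index arrays (one per chain copy). For carbon j (2..n-1) the vector
    C(j-1)->C(j+1) defines theta_j against z; terminal carbons have no
    skeletal axis and are excluded. Averages run over frames and copies.
    """
    if isinstance(traj_or_frame, Frame):
        coords = traj_or_frame.coordinates[None, :, :]
    else:
        coords = traj_or_frame.coordinates
    rows = []
    for key, copies in chains.items():
        ncarb = len(copies[0])
        if ncarb < 3:
            raise StructureError(f"chain {key!r} has fewer than 3 carbons")
        idx = np.asarray(copies)                       # copies x ncarb
        pos = coords[:, idx, :]                        # F x copies x n x 3
        v = pos[:, :, 2:, :] - pos[:, :, :-2, :]       # skeletal vectors
        cos = v[..., 2] / np.linalg.norm(v, axis=-1)
        s = 0.5 * (3.0 * cos ** 2 - 1.0)               # F x copies x (n-2)
        for j in range(ncarb - 2):
            vals = s[:, :, j].ravel()
            rows.append({"chain": key, "carbon": j + 2,
                         "scd": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1
                         else 0.0,
                         "n": int(len(vals))})
    return OrderParameterProfile(pd.DataFrame(rows))


def pooled_fatty_acid_average(profile: OrderParameterProfile,
                              classes: dict[str, list[str]]) -> pd.DataFrame:
    """Pool chain-average S_CD over chains of the same fatty-acid class."""
    per_chain = profile.per_chain_average()
    rows = []
    for cls, members in classes.items():
        sel = per_chain[per_chain["chain"].isin(members)]
        if len(sel):
            rows.append({"class": cls, "scd": float(sel["scd"].mean()),
                         "n_chains": int(len(sel))})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- tail angles

def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cos = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def _inward_normal(leaflet: np.ndarray) -> np.ndarray:
    nz = np.where(np.asarray(leaflet) == "outer", -1.0, 1.0)
    out = np.zeros((len(nz), 3))
    out[:, 2] = nz
    return out


@dataclass
class AngleSet:
    """Distributions and Table-style means of the tail-geometry angles."""

    distributions: dict[str, np.ndarray]
    summary: pd.DataFrame  # angle, leaflet, mean, sd, n
    skipped: int = 0


def chain_angles(markers: dict, leaflet, pivots: dict | None = None,
                 cholesterol: dict | None = None,
                 max_skip_fraction: float = 0.5) -> AngleSet:
    """Tail tilt/splay/bend angles from per-lipid marker coordinates.

    ``markers`` holds (n_lipids, 3) arrays for keys P, sn1_ch3, sn2_ch3,
    sn1_cooh, sn2_cooh (missing markers as NaN rows). ``pivots`` maps a
    label suffix ('1', '2') to the (n, 3) pivot-carbon positions on the
    sn-2 chain (first vs second oxidation-prone carbon), giving gamma2_1 /
    gamma2_2 and delta2_1 / delta2_2. ``cholesterol`` supplies {'o3':
    (m,3), 'c17': (m,3), 'leaflet': (m,)} ring-axis endpoints for alpha3.

    Angle conventions: alpha/delta against the per-leaflet inward normal
    (0 = pointing into the core); beta between the two P->CH3 vectors;
    gamma is the interior angle at the pivot (straight chain = 180).
    """
    leaflet = np.asarray(leaflet)
    normal = _inward_normal(leaflet)
    P = np.asarray(markers["P"], float)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    skipped = 0
    total = 0

    def record(name, values, leaf):
        out[name] = (values, leaf)

    def tilt(name, end):
        nonlocal skipped, total
        v = np.asarray(end, float) - P
        ok = np.all(np.isfinite(v), axis=1)
        skipped += int((~ok).sum())
        total += len(ok)
        record(name, _angle_deg(v[ok], normal[ok]), leaflet[ok])

    tilt("alpha1", markers["sn1_ch3"])
    tilt("alpha2", markers["sn2_ch3"])
    tilt("delta1", markers["sn1_cooh"])

    v1 = np.asarray(markers["sn1_ch3"], float) - P
    v2 = np.asarray(markers["sn2_ch3"], float) - P
    ok = np.all(np.isfinite(v1), axis=1) & np.all(np.isfinite(v2), axis=1)
    record("beta", _angle_deg(v1[ok], v2[ok]), leaflet[ok])

    def interior(name, pivot, end):
        nonlocal skipped, total
        pivot = np.asarray(pivot, float)
        a = P - pivot
        b = np.asarray(end, float) - pivot
        ok = np.all(np.isfinite(a), axis=1) & np.all(np.isfinite(b), axis=1)
        skipped += int((~ok).sum())
        total += len(ok)
        record(name, _angle_deg(a[ok], b[ok]), leaflet[ok])

    interior("gamma1", markers["sn1_cooh"], markers["sn1_ch3"])
    if pivots:
        for suffix, pivot in pivots.items():
            interior(f"gamma2_{suffix}", pivot, markers["sn2_ch3"])
            tilt(f"delta2_{suffix}", pivot)

    if cholesterol is not None:
        axis = np.asarray(cholesterol["c17"], float) \
            - np.asarray(cholesterol["o3"], float)
        cleaf = np.asarray(cholesterol["leaflet"])
        ok = np.all(np.isfinite(axis), axis=1)
        record("alpha3", _angle_deg(axis[ok], _inward_normal(cleaf)[ok]),
               cleaf[ok])

    if total and skipped / total > max_skip_fraction:
        raise StructureError(
            f"{skipped}/{total} lipids missing markers (> "
            f"{max_skip_fraction:.0%})")

    rows = []
    dists = {}
    for name, (vals, leaf) in out.items():
        dists[name] = vals
        for l in np.unique(leaf):
            sel = vals[leaf == l]
            rows.append({"angle": name, "leaflet": l,
                         "mean": float(sel.mean()) if len(sel) else math.nan,
                         "sd": float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
                         "n": int(len(sel))})
    return AngleSet(dists, pd.DataFrame(rows), skipped)


def assign_leaflets(traj: Trajectory, head_names=("P", "O3"),
                    frame_index: int = 0) -> pd.Series:
    """Tag each residue inner/outer by its head-marker z relative to the
    membrane COM at one frame; lipids are never reassigned mid-analysis."""
    atoms = traj.atoms
    z = traj.coordinates[frame_index, :, 2]
    masses = atoms["mass"].to_numpy(float)
    zc = np.average(z, weights=masses)
    heads = atoms["name"].isin(head_names)
    if not heads.any():
        raise StructureError("no head-marker atoms found")
    side = pd.Series(np.where(z >= zc, "outer", "inner"), index=atoms.index)
    per_res = side[heads].groupby(atoms.loc[heads, "resid"]).first()
    return atoms["resid"].map(per_res)
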