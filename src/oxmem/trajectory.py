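"""Coordinate, trajectory and umbrella-window time-series containers and I/O.

Internal units are nm/ps/amu everywhere; readers convert on ingest (PDB
angstroms -> nm, GRO already nm). Binary trajectory formats (XTC, DCD) and
the coordinate formats (PDB, GRO) are read and written through MDAnalysis;
umbrella-window time series use the GROMACS pullx text dialect (two columns,
'#'/'@' comment lines) with a JSON sidecar carrying the window center and
force constant. Boxes are orthorhombic only. Coordinates are stored as
found (wrapped); unwrapping is an explicit downstream operation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class TrajectoryError(ValueError):
    """Malformed or unsupported coordinate/trajectory input."""


@dataclass
class Frame:
    """One configuration: N x 3 coordinates (nm), orthorhombic box (nm),
    timestamp (ps)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        self.box = np.asarray(self.box, float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("coordinates must be N x 3")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("non-finite coordinates")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise TrajectoryError("box must be 3 strictly positive lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom set with per-atom metadata.

    ``coordinates`` is (n_frames, n_atoms, 3) in nm, ``boxes`` is
    (n_frames, 3), ``times`` strictly increasing ps. ``atoms`` is a
    DataFrame with at least resid, resname, name, mass columns; species
    and leaflet tags ride along when known.
    """

    coordinates: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        self.boxes = np.asarray(self.boxes, float)
        self.times = np.asarray(self.times, float)
        if self.coordinates.ndim != 3:
            raise TrajectoryError("coordinates must be F x N x 3")
        if len(self.times) != len(self.coordinates):
            raise TrajectoryError("times and frames disagree")
        if len(self.times) == 0:
            raise TrajectoryError("empty trajectory")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("times must be strictly increasing")
        if len(self.atoms) != self.coordinates.shape[1]:
            raise TrajectoryError(
                f"atom metadata ({len(self.atoms)}) does not match "
                f"coordinates ({self.coordinates.shape[1]} atoms)")
        if "mass" in self.atoms and not np.all(self.atoms["mass"] > 0):
            raise TrajectoryError("masses must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], self.times[i])


@dataclass
class WindowSeries:
    """Biased samples from one umbrella window: reaction-coordinate
    positions (nm) over time (ps), plus the harmonic bias parameters.
    Optional instantaneous constraint/restraint forces (kJ/mol/nm)."""

    window_center: float
    force_constant: float  # kJ/mol/nm^2
    times: np.ndarray
    positions: np.ndarray
    forces: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if self.force_constant < 0:
            raise TrajectoryError("force constant must be >= 0")
        if len(self.positions) == 0:
            raise TrajectoryError("window series must be non-empty")
        if len(self.times) != len(self.positions):
            raise TrajectoryError("times/positions length mismatch")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, float)
            if len(self.forces) != len(self.positions):
                raise TrajectoryError("forces length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.positions)


# --------------------------------------------------------------- helpers

def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _check_orthorhombic(dimensions, path):
    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        raise TrajectoryError(f"{path}: missing or degenerate box")
    alpha, beta, gamma = dimensions[3:6]
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise TrajectoryError(
            f"{path}: triclinic boxes are unsupported "
            f"(angles {alpha:.1f}/{beta:.1f}/{gamma:.1f})")


def _atoms_dataframe(universe) -> pd.DataFrame:
    ag = universe.atoms
    n = len(ag)

    def get(attr, default):
        try:
            return getattr(ag, attr)
        except Exception:
            return np.full(n, default)

    return pd.DataFrame({
        "resid": get("resids", 0),
        "resname": get("resnames", "UNK"),
        "name": get("names", "X"),
        "mass": np.where(get("masses", 1.0) > 0, get("masses", 1.0), 1.0),
    })


def _prescan_gro(path: Path):
    """Cheap structural scan of a GRO file so parse failures can name the
    offending line."""
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise TrajectoryError(f"{path}: truncated at line {len(lines)}: "
                              "missing atom-count line")
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise TrajectoryError(f"{path}: line 2: atom count is not an integer")
    expected = n + 3  # title, count, atoms, box
    if len(lines) < expected:
        raise TrajectoryError(
            f"{path}: truncated at line {len(lines)}: expected {expected} "
            f"lines for {n} atoms")


def read_coordinates(path, fmt: str | None = None):
    """Read a single PDB or GRO configuration.

    Returns (Frame, atoms DataFrame); coordinates in nm regardless of the
    source unit (PDB angstrom -> nm conversion applied).
    """
    mda = _import_mda()
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise TrajectoryError(f"unsupported coordinate format {fmt!r}")
    if fmt == "GRO":
        _prescan_gro(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except TrajectoryError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise TrajectoryError(f"{path}: failed to parse as {fmt}: {exc}")
    _check_orthorhombic(u.dimensions, path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0)
    frame = Frame(u.atoms.positions / 10.0, u.dimensions[:3] / 10.0, time=t)
    return frame, _atoms_dataframe(u)


def write_coordinates(frame: Frame, atoms: pd.DataFrame, path,
                      fmt: str | None = None) -> None:
    """Write a single configuration as PDB or GRO."""
    mda = _import_mda()
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    u = _build_universe(atoms, frame.n_atoms)
    u.atoms.positions = frame.coordinates * 10.0
    u.dimensions = np.array([*(frame.box * 10.0), 90.0, 90.0, 90.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _build_universe(atoms: pd.DataFrame, n_atoms: int, n_frames: int = 1):
    mda = _import_mda()
    resids = atoms["resid"].to_numpy() if "resid" in atoms else \
        np.arange(1, n_atoms + 1)
    uniq, residx = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(n_atoms, n_residues=len(uniq),
                           atom_resindex=residx, trajectory=True)
    u.add_TopologyAttr("names", [str(x)[:4] for x in atoms.get(
        "name", pd.Series(["X"] * n_atoms))])
    resnames = []
    if "resname" in atoms:
        for r in uniq:
            resnames.append(str(atoms.loc[resids == r, "resname"].iloc[0])[:4])
    else:
        resnames = ["UNK"] * len(uniq)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", uniq.astype(int))
    if "mass" in atoms:
        u.add_TopologyAttr("masses", atoms["mass"].to_numpy(float))
    return u


def write_trajectory(traj: Trajectory, topology_path, trajectory_path) -> None:
    """Write a Trajectory as a GRO/PDB topology plus an XTC or DCD file."""
    mda = _import_mda()
    write_coordinates(traj.frame(0), traj.atoms, topology_path)
    u = _build_universe(traj.atoms, traj.n_atoms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(trajectory_path), traj.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[i] * 10.0
                u.dimensions = np.array(
                    [*(traj.boxes[i] * 10.0), 90.0, 90.0, 90.0])
                u.trajectory.ts.time = traj.times[i]
                w.write(u.atoms)


def read_trajectory(topology_path, trajectory_path,
                    atoms: pd.DataFrame | None = None) -> Trajectory:
    """Read a binary trajectory (XTC/DCD) against a PDB/GRO topology.

    Optional ``atoms`` overrides the metadata parsed from the topology
    (e.g. to restore species/leaflet tags from a sidecar).
    """
    mda = _import_mda()
    top, traj_p = Path(topology_path), Path(trajectory_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u_top = mda.Universe(str(top))
    n_top = len(u_top.atoms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(top), str(traj_p))
            n_traj = u.trajectory.n_atoms
    except Exception as exc:  # noqa: BLE001
        n_traj = _peek_trajectory_atoms(traj_p)
        raise TrajectoryError(
            f"atom-count mismatch or unreadable trajectory: topology "
            f"{top} has {n_top} atoms, trajectory {traj_p} has "
            f"{n_traj if n_traj is not None else 'unknown'} ({exc})")
    if n_traj != n_top:
        raise TrajectoryError(
            f"atom-count mismatch: topology {n_top}, trajectory {n_traj}")
    coords, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            _check_orthorhombic(ts.dimensions, traj_p)
            coords.append(u.atoms.positions / 10.0)
            boxes.append(ts.dimensions[:3] / 10.0)
            times.append(float(ts.time))
    if not coords:
        raise TrajectoryError(f"{traj_p}: empty trajectory")
    meta = atoms if atoms is not None else _atoms_dataframe(u_top)
    return Trajectory(np.array(coords), np.array(boxes), np.array(times),
                      meta)


def _peek_trajectory_atoms(path: Path):
    mda = _import_mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = mda.coordinates.core.reader(str(path))
            return reader.n_atoms
    except Exception:  # noqa: BLE001
        return None


# --------------------------------------------------- pullx window series

def read_window_series(paths, sidecars=None) -> list[WindowSeries]:
    """Read GROMACS pullx-dialect time/position files into WindowSeries.

    Each data file needs a JSON sidecar (default: same stem + '.json')
    providing at least ``window_center`` and ``force_constant``; an
    optional third data column is read as restraint force.
    """
    out = []
    paths = [Path(p) for p in paths]
    if sidecars is None:
        sidecars = [p.with_suffix(".json") for p in paths]
    for path, side in zip(paths, sidecars):
        side = Path(side)
        if not side.exists():
            raise TrajectoryError(
                f"{path}: missing sidecar {side} with window center and "
                "force constant")
        meta = json.loads(side.read_text())
        for key in ("window_center", "force_constant"):
            if key not in meta:
                raise TrajectoryError(f"{side}: missing {key!r}")
        rows = []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            s = line.strip()
            if not s or s.startswith(("#", "@", ";")):
                continue
            parts = s.split()
            try:
                rows.append([float(x) for x in parts[:3]])
            except ValueError:
                raise TrajectoryError(
                    f"{path}: line {lineno}: non-numeric payload {s!r}")
        if not rows:
            raise TrajectoryError(f"{path}: no samples")
        ncol = min(len(r) for r in rows)
        arr = np.array([r[:ncol] for r in rows], float)
        forces = arr[:, 2] if ncol >= 3 else None
        out.append(WindowSeries(float(meta["window_center"]),
                                float(meta["force_constant"]),
                                arr[:, 0], arr[:, 1], forces))
    return out


def write_window_series(windows: list[WindowSeries], directory,
                        prefix: str = "window") -> list[Path]:
    """Write WindowSeries as pullx-style text plus JSON sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, w in enumerate(windows):
        path = directory / f"{prefix}{i:03d}.xvg"
        cols = [w.times, w.positions]
        header = "# pullx: time (ps), position (nm)"
        if w.forces is not None:
            cols.append(w.forces)
            header += ", force (kJ/mol/nm)"
        np.savetxt(path, np.column_stack(cols), header=header, comments="")
        path.with_suffix(".json").write_text(json.dumps({
            "window_center": w.window_center,
            "force_constant": w.force_constant}))
        paths.append(path)
    return paths
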