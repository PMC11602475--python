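"""Geometric hydrogen-bond detection and per-OOH-group bonding rates.

A donor-H / acceptor pair is bonded when the donor-acceptor distance is
within ``max_da_distance`` and the H-D...A angle (at the donor, between
the D->H and D->A directions) is within ``max_hda_angle``, both under
minimum-image periodic boundary conditions. The defaults (0.35 nm, 30
degrees) are the de-facto standard geometric definition in MD tooling;
both knobs are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Frame, Trajectory


class HBondError(ValueError):
    """Invalid donor/acceptor specification."""


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 0.35  # nm
    max_hda_angle: float = 30.0    # degrees

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise HBondError("distance cutoff must be positive")
        if not 0.0 < self.max_hda_angle <= 90.0:
            raise HBondError("angle cutoff must be in (0, 90] degrees")


def _min_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - np.round(vec / box) * box


def detect_hbonds(frame: Frame, donors, acceptors,
                  criteria: HBondCriteria | None = None) -> list[tuple]:
    """All (D, H, A) triplets satisfying the geometric criteria.

    ``donors`` is a sequence of (donor_index, hydrogen_index) pairs (the
    donor must carry an explicit hydrogen); ``acceptors`` an index array.
    Distances use minimum-image convention; a cell tree accelerates the
    distance search.
    """
    criteria = criteria or HBondCriteria()
    donors = list(donors)
    acceptors = np.asarray(acceptors, int)
    for d, h in donors:
        if h is None:
            raise HBondError(f"donor atom {d} has no explicit hydrogen")
    if not donors or len(acceptors) == 0:
        return []
    box = frame.box
    pos = np.mod(frame.coordinates, box)  # KD-tree needs in-box positions
    tree = cKDTree(pos[acceptors], boxsize=box)
    d_idx = np.array([d for d, _ in donors])
    h_idx = np.array([h for _, h in donors])
    neighbor_lists = tree.query_ball_point(pos[d_idx],
                                           criteria.max_da_distance)
    cos_cut = np.cos(np.radians(criteria.max_hda_angle))
    bonds = []
    for (d, h, neigh) in zip(d_idx, h_idx, neighbor_lists):
        if not neigh:
            continue
        a = acceptors[np.asarray(neigh, int)]
        a = a[a != d]
        if len(a) == 0:
            continue
        da = _min_image(frame.coordinates[a] - frame.coordinates[d], box)
        dh = _min_image(frame.coordinates[h] - frame.coordinates[d], box)
        dist = np.linalg.norm(da, axis=1)
        cos = (da @ dh) / (dist * np.linalg.norm(dh))
        ok = (dist <= criteria.max_da_distance) & (cos >= cos_cut)
        bonds.extend((int(d), int(h), int(ai)) for ai in a[ok])
    return bonds


@dataclass
class OOHGroup:
    """One hydroperoxyl group class: donor (O-H) plus two acceptor
    oxygens per instance.

    ``key`` names the oxidized position (e.g. 'sn2-LA13'), instances are
    (O_hydroxyl, H, O_peroxy) atom-index triplets.
    """

    key: str
    leaflet: str
    instances: list[tuple[int, int, int]]

    @property
    def donors(self) -> list[tuple[int, int]]:
        return [(o1, h) for o1, h, _ in self.instances]

    @property
    def acceptors(self) -> np.ndarray:
        return np.array([[o1, o2] for o1, _, o2 in self.instances]).ravel() \
            if self.instances else np.empty(0, int)


@dataclass
class PartnerClass:
    """A polar-interface partner class: acceptor atoms plus optional
    donor (D, H) pairs (e.g. water contributes both)."""

    acceptors: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    donors: list[tuple[int, int]] = field(default_factory=list)


def hbond_rates(traj: Trajectory, groups: list[OOHGroup],
                partners: dict[str, PartnerClass],
                criteria: HBondCriteria | None = None) -> pd.DataFrame:
    """Mean hydrogen bonds per frame between each OOH group class and
    each partner class, normalized per group instance.

    Bonds are counted in both directions (OOH donates to the partner's
    acceptors; the partner's donors donate to the OOH oxygens). Empty
    groups yield a zero-rate row flagged with n_instances=0.
    """
    criteria = criteria or HBondCriteria()
    rows = []
    for g in groups:
        n_inst = len(g.instances)
        for pname, pc in partners.items():
            total = 0
            if n_inst:
                for f in range(traj.n_frames):
                    frame = traj.frame(f)
                    total += len(detect_hbonds(
                        frame, g.donors, pc.acceptors, criteria))
                    if pc.donors:
                        total += len(detect_hbonds(
                            frame, pc.donors, g.acceptors, criteria))
            rate = total / traj.n_frames / n_inst if n_inst else 0.0
            rows.append({"group": g.key, "leaflet": g.leaflet,
                         "partner": pname, "rate": rate,
                         "n_instances": n_inst,
                         "flagged_empty": n_inst == 0})
    return pd.DataFrame(rows)
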