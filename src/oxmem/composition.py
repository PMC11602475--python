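"""Membrane composition models: native erythrocyte bilayer and its
ferroptosis (hydroperoxide-substituted) derivative.

The packaged default table is a reconstruction of the asymmetric red-blood-
cell membrane model: 200 phospholipids (including sphingomyelins) plus 100
cholesterol at a 0.5 cholesterol:phospholipid molar ratio, split into an
inner leaflet of 157 lipids and an outer leaflet of 143, with PE/PS
enriched inside and PC/SM outside. The ferroptosis membrane replaces every
PUFA-bearing phospholipid by hydroperoxide (Hpd) derivatives: species with
a single LA/AA/DHA chain split 50/50 between the two positional isomers
(9/13-HPODE, 12/15-HPETE, 14/17-HPDHA) and di-PUFA species map to the
sn-1/sn-2 isomer pair 13/9, 15/12 and 17/14.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import (CompositionError, LipidSpecies, SPECIES,
                      HPD_POSITIONS, oxidized_species)

LEAFLETS = ("inner", "outer")

# Reconstructed default per-leaflet composition (species, count).
_DEFAULT_TABLE = """\
leaflet,species,count
inner,PLPE,2
inner,SLPE,2
inner,PLPC,2
inner,SLPS,2
inner,SAPE,6
inner,SAPC,2
inner,SAPS,2
inner,SDPE,2
inner,ODPE,4
inner,SDPS,2
inner,DLPE,1
inner,DLPC,1
inner,DAPE,1
inner,DAPC,1
inner,DAPS,1
inner,DDPE,1
inner,DDPS,1
inner,POPE,30
inner,DPPE,14
inner,POPC,8
inner,DPPC,4
inner,DSPS,6
inner,SOPS,8
inner,PSM,2
inner,SSM,1
inner,LSM,1
inner,CHOL,50
outer,SLPE,2
outer,PLPC,2
outer,SLPC,2
outer,OLPC,2
outer,LNSM,2
outer,SAPE,4
outer,SAPC,6
outer,SAPS,2
outer,SDPE,2
outer,SDPC,4
outer,DSM,2
outer,DLPC,1
outer,DAPE,1
outer,DAPC,1
outer,DDPE,1
outer,POPE,4
outer,DPPE,2
outer,POPC,16
outer,DPPC,8
outer,PSM,10
outer,SSM,8
outer,LSM,4
outer,BSM,4
outer,NSM,3
outer,CHOL,50
"""


def default_native_table() -> pd.DataFrame:
    """The packaged default per-leaflet composition table."""
    return pd.read_csv(io.StringIO(_DEFAULT_TABLE))


@dataclass
class MembraneComposition:
    """Per-leaflet species inventory with integer counts."""

    leaflets: dict[str, list[tuple[LipidSpecies, int]]]
    label: str = "native"

    def __post_init__(self):
        for leaf in self.leaflets:
            if leaf not in LEAFLETS:
                raise CompositionError(f"unknown leaflet {leaf!r}")
            for sp, n in self.leaflets[leaf]:
                if not isinstance(n, (int, np.integer)) or n <= 0:
                    raise CompositionError(
                        f"count for {sp.name} in {leaf} must be a positive "
                        f"integer, got {n!r}")

    # -- bookkeeping -----------------------------------------------------
    def leaflet_total(self, leaflet: str, phospholipids_only=False) -> int:
        return sum(n for sp, n in self.leaflets[leaflet]
                   if not (phospholipids_only and sp.headgroup_class == "CHOL"))

    @property
    def total_lipids(self) -> int:
        return sum(self.leaflet_total(l) for l in self.leaflets)

    @property
    def total_phospholipids(self) -> int:
        return sum(self.leaflet_total(l, phospholipids_only=True)
                   for l in self.leaflets)

    @property
    def total_cholesterol(self) -> int:
        return self.total_lipids - self.total_phospholipids

    @property
    def total_charge(self) -> int:
        return sum(sp.formal_charge * n
                   for l in self.leaflets for sp, n in self.leaflets[l])

    def species_counts(self, leaflet: str | None = None) -> dict[str, int]:
        leaves = [leaflet] if leaflet else list(self.leaflets)
        out: dict[str, int] = {}
        for l in leaves:
            for sp, n in self.leaflets[l]:
                out[sp.name] = out.get(sp.name, 0) + n
        return out


def build_composition(table: pd.DataFrame, label: str = "native"
                      ) -> MembraneComposition:
    """Build a composition from a (leaflet, species, count) table."""
    required = {"leaflet", "species", "count"}
    if table is None or len(table) == 0:
        raise CompositionError("empty composition table")
    if not required.issubset(table.columns):
        raise CompositionError(
            f"table must have columns {sorted(required)}")
    leaflets: dict[str, list[tuple[LipidSpecies, int]]] = {
        l: [] for l in LEAFLETS}
    for _, row in table.iterrows():
        leaf = str(row["leaflet"])
        if leaf not in LEAFLETS:
            raise CompositionError(f"unknown leaflet label {leaf!r}")
        code = str(row["species"])
        if code not in SPECIES:
            raise CompositionError(f"unknown species code {code!r}")
        raw = row["count"]
        if float(raw) != int(raw):
            raise CompositionError(
                f"count for {code} must be an integer, got {raw!r}")
        leaflets[leaf].append((SPECIES[code], int(raw)))
    leaflets = {l: v for l, v in leaflets.items() if v}
    return MembraneComposition(leaflets, label=label)


def build_native_composition(table: pd.DataFrame | None = None
                             ) -> MembraneComposition:
    """Build the native membrane (default: the packaged reconstruction)."""
    if table is None:
        table = default_native_table()
    comp = build_composition(table, label="native")
    for l in comp.leaflets:
        for sp, _ in comp.leaflets[l]:
            if sp.is_oxidized:
                raise CompositionError(
                    f"native composition contains oxidized species {sp.name}")
    return comp


def to_table(comp: MembraneComposition) -> pd.DataFrame:
    """Serialize a composition back to a (leaflet, species, count) table."""
    rows = [(l, sp.name, n)
            for l in comp.leaflets for sp, n in comp.leaflets[l]]
    return pd.DataFrame(rows, columns=["leaflet", "species", "count"])


# ------------------------------------------------------------ substitution

@dataclass(frozen=True)
class SubstitutionRules:
    """How PUFA chains map to their hydroperoxide isomers.

    ``single_pufa_split`` maps a PUFA class to (position A, position B,
    fraction going to A); ``double_pufa_assignment`` maps it to the
    (sn-1, sn-2) oxidized-carbon pair. ``rounding_policy`` resolves odd
    counts under the 50/50 split: 'half_up' rounds half up for isomer A,
    'random' flips a seeded coin per species entry.
    """

    single_pufa_split: dict[str, tuple[int, int, float]] = field(
        default_factory=lambda: {
            cls: (lo, hi, 0.5) for cls, (lo, hi) in HPD_POSITIONS.items()})
    double_pufa_assignment: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            cls: (hi, lo) for cls, (lo, hi) in HPD_POSITIONS.items()})
    rounding_policy: str = "half_up"

    def __post_init__(self):
        for cls, (_, _, f) in self.single_pufa_split.items():
            if not 0.0 <= f <= 1.0:
                raise CompositionError(f"fraction for {cls} outside [0,1]")
        if self.rounding_policy not in ("half_up", "random"):
            raise CompositionError(
                f"unknown rounding policy {self.rounding_policy!r}")


def apply_ferroptosis_substitution(
        native: MembraneComposition,
        rules: SubstitutionRules | None = None,
        seed: int = 0) -> MembraneComposition:
    """Replace every PUFA-bearing species by its Hpd derivative(s).

    Lipid counts are conserved per leaflet; non-PUFA species pass through
    unchanged.
    """
    if native.label != "native":
        raise CompositionError("substitution expects a native composition")
    rules = rules or SubstitutionRules()
    rng = np.random.default_rng(seed)
    leaflets: dict[str, list[tuple[LipidSpecies, int]]] = {}
    for leaf, entries in native.leaflets.items():
        out: list[tuple[LipidSpecies, int]] = []
        for sp, n in entries:
            if not sp.is_pufa:
                out.append((sp, n))
                continue
            cls = sp.pufa_class
            if sp.n_pufa_chains == 2:
                if cls not in rules.double_pufa_assignment:
                    raise CompositionError(
                        f"no double-PUFA rule covers species {sp.name}")
                p1, p2 = rules.double_pufa_assignment[cls]
                out.append((oxidized_species(sp, p1, p2), n))
            else:
                if cls not in rules.single_pufa_split:
                    raise CompositionError(
                        f"no single-PUFA rule covers species {sp.name}")
                pa, pb, fa = rules.single_pufa_split[cls]
                exact = n * fa
                if rules.rounding_policy == "half_up":
                    na = math.floor(exact + 0.5)
                else:
                    na = math.floor(exact)
                    if exact - na > 0 and rng.random() < 0.5:
                        na += 1
                nb = n - na
                # the single PUFA chain sits in sn-2 (or the SM N-acyl)
                sn1_pos = None if (sp.sn2 and sp.sn2.is_pufa) else pa
                for pos, cnt in ((pa, na), (pb, nb)):
                    if cnt == 0:
                        continue
                    if sn1_pos is None:
                        out.append((oxidized_species(sp, None, pos), cnt))
                    else:
                        out.append((oxidized_species(sp, pos, None), cnt))
        leaflets[leaf] = out
    return MembraneComposition(leaflets, label="ferroptosis")


# ----------------------------------------------------------------- audits

def composition_summary(comp: MembraneComposition) -> dict:
    """Audit tables: mole fractions by species, headgroup, fatty-acid
    class and oxidation state, plus the cholesterol:phospholipid ratio."""
    rows = []
    for leaf in comp.leaflets:
        total = comp.leaflet_total(leaf)
        for sp, n in comp.leaflets[leaf]:
            rows.append({
                "leaflet": leaf, "species": sp.name,
                "headgroup": sp.headgroup_class,
                "oxidized": sp.is_oxidized,
                "fatty_acids": "/".join(c.fatty_acid_class
                                        for c in sp.chains) or "-",
                "count": n,
                "mole_fraction": n / total,
            })
    by_species = pd.DataFrame(rows)
    whole = (by_species.groupby("species", as_index=False)["count"].sum())
    whole["mole_fraction"] = whole["count"] / comp.total_lipids
    by_headgroup = (by_species.groupby(["leaflet", "headgroup"],
                                       as_index=False)["count"].sum())
    by_headgroup["mole_fraction"] = [
        n / comp.leaflet_total(l)
        for l, n in zip(by_headgroup["leaflet"], by_headgroup["count"])]
    by_oxidation = (by_species.groupby(["leaflet", "oxidized"],
                                       as_index=False)["count"].sum())
    n_pl = comp.total_phospholipids
    return {
        "by_species": by_species,
        "whole_membrane": whole,
        "by_headgroup": by_headgroup,
        "by_oxidation": by_oxidation,
        "totals": {
            "phospholipids": n_pl,
            "cholesterol": comp.total_cholesterol,
            "lipids": comp.total_lipids,
            "per_leaflet": {l: comp.leaflet_total(l) for l in comp.leaflets},
            "charge": comp.total_charge,
        },
        "cholesterol_phospholipid_ratio": comp.total_cholesterol / n_pl,
    }


def hpd_mole_percent(comp: MembraneComposition) -> dict[str, float]:
    """Mole percent of each hydroperoxide species class, relative to the
    total phospholipid count (the convention of the composition model)."""
    n_pl = comp.total_phospholipids
    out: dict[str, float] = {}
    for leaf in comp.leaflets:
        for sp, n in comp.leaflets[leaf]:
            if not sp.is_oxidized:
                continue
            if sp.n_pufa_chains == 2:
                lo, hi = HPD_POSITIONS[sp.pufa_class]
                key = f"double-{sp.pufa_class}{hi},{lo}"
            else:
                chain = sp.sn2 if (sp.sn2 and sp.sn2.is_oxidized) else sp.sn1
                key = f"single-{sp.pufa_class}{chain.ooh_positions[0]}"
            out[key] = out.get(key, 0.0) + 100.0 * n / n_pl
    return out


# -------------------------------------------------------- toy coordinates

#: marker template per lipid: (atom name template, mass amu, depth nm from
#: the leaflet head plane toward the bilayer center)
_MARKER_DEPTHS = (("head", 31.0, 0.0), ("carbonyl", 12.0, 0.5),
                  ("mid", 12.0, 1.0), ("methyl", 15.0, 1.6))


def place_toy_coordinates(comp: MembraneComposition,
                          box: tuple[float, float, float],
                          tolerance: float = 0.2,
                          seed: int = 0,
                          half_thickness: float = 2.0):
    """Place coarse marker atoms for every lipid on a jittered leaflet
    lattice, honoring a minimum inter-marker distance (``tolerance``).

    Marker resolution only: one head marker (P, or O3 for cholesterol),
    a carbonyl carbon, a mid-chain carbon and a terminal methyl per lipid,
    stacked along z. Raises after bounded retries if the requested counts
    cannot be packed into the box at the given tolerance.
    """
    from scipy.spatial import cKDTree
    from .trajectory import Frame

    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    depth_step = max(0.5, 1.05 * tolerance)
    records = []
    coords = []
    resid = 0
    for leaf, sign in (("inner", -1.0), ("outer", +1.0)):
        if leaf not in comp.leaflets:
            continue
        lipids = [sp for sp, n in comp.leaflets[leaf] for _ in range(n)]
        n = len(lipids)
        ncols = math.ceil(math.sqrt(n))
        pitch = min(box[0], box[1]) / ncols
        if pitch < tolerance:
            raise CompositionError(
                f"cannot pack {n} lipids in a {box[0]}x{box[1]} nm leaflet "
                f"at tolerance {tolerance} nm")
        for attempt in range(5):
            jitter = (pitch - tolerance) / (4.0 * (attempt + 1))
            pts = []
            rec = []
            for i, sp in enumerate(lipids):
                gx, gy = divmod(i, ncols)
                x = (gx + 0.5) * pitch + rng.uniform(-jitter, jitter)
                y = (gy + 0.5) * pitch + rng.uniform(-jitter, jitter)
                markers = (_MARKER_DEPTHS[:1] if sp.headgroup_class == "CHOL"
                           else _MARKER_DEPTHS)
                for j, (kind, mass, _) in enumerate(markers):
                    z = sign * (half_thickness - j * depth_step)
                    name = "O3" if sp.headgroup_class == "CHOL" else \
                        {"head": "P", "carbonyl": "C1", "mid": "C8",
                         "methyl": "C16"}[kind]
                    pts.append((x % box[0], y % box[1], z))
                    rec.append((resid + i + 1, sp.name, name, mass,
                                sp.name, leaf))
            pts = np.asarray(pts)
            tree = cKDTree(pts)
            dmin = tree.query(pts, k=2)[0][:, 1].min() if len(pts) > 1 \
                else np.inf
            if dmin >= tolerance:
                break
        else:
            raise CompositionError(
                "toy placement failed to honor tolerance after retries")
        coords.append(pts)
        records.extend(rec)
        resid += n
    atoms = pd.DataFrame(records, columns=[
        "resid", "resname", "name", "mass", "species", "leaflet"])
    frame = Frame(np.vstack(coords), box, time=0.0)
    return frame, atoms
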