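"""Lipid species vocabulary for the erythrocyte-membrane models.

Species codes follow the two-letter acyl-chain prefix convention
(P=palmitoyl 16:0, S=stearoyl 18:0, O=oleoyl 18:1, L=linoleoyl 18:2,
A=arachidonoyl 20:4, D=docosahexaenoyl 22:6) plus the headgroup class,
e.g. PLPE = 1-palmitoyl-2-linoleoyl-PE. Sphingomyelins are named by their
single N-acyl chain (PSM, SSM, LNSM, LSM, BSM, NSM, DSM). Oxidized
(hydroperoxide, "Hpd") derivatives append the oxidized carbon position:
PLPE9 carries 9-HPODE in sn-2, DLPE9,13 carries 13-HPODE/9-HPODE in
sn-1/sn-2. Phosphatidylinositol is not in the vocabulary: the membrane
model replaces it with PS (both carry a single negative charge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class CompositionError(ValueError):
    """Invalid composition table, species code, or substitution rule."""


@dataclass(frozen=True)
class ChainSpec:
    """One acyl chain: carbon count, double bonds, and -OOH positions.

    Double bonds are (position, geometry) with geometry 'cis' or 'trans';
    positions index the first carbon of the bond, 1-based from the
    carbonyl carbon. ``ooh_positions`` lists carbons bearing a
    hydroperoxyl group (empty for non-oxidized chains).
    """

    carbon_count: int
    double_bonds: tuple[tuple[int, str], ...] = ()
    ooh_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if self.carbon_count < 2:
            raise CompositionError("chain needs at least 2 carbons")
        last = 0
        for pos, geom in self.double_bonds:
            if not 1 <= pos <= self.carbon_count:
                raise CompositionError(
                    f"double bond position {pos} outside 1..{self.carbon_count}")
            if pos <= last:
                raise CompositionError("double-bond positions must increase")
            if geom not in ("cis", "trans"):
                raise CompositionError(f"bad geometry {geom!r}")
            last = pos
        for pos in self.ooh_positions:
            if not 1 <= pos <= self.carbon_count:
                raise CompositionError(
                    f"OOH position {pos} outside 1..{self.carbon_count}")

    @property
    def n_double_bonds(self) -> int:
        return len(self.double_bonds)

    @property
    def is_pufa(self) -> bool:
        return self.n_double_bonds >= 2

    @property
    def is_oxidized(self) -> bool:
        return len(self.ooh_positions) > 0

    @property
    def fatty_acid_class(self) -> str:
        """Coarse fatty-acid class, keyed on (carbons, unsaturation)."""
        key = (self.carbon_count, self.n_double_bonds)
        return _FA_CLASS.get(key, f"{self.carbon_count}:{self.n_double_bonds}")


_FA_CLASS = {
    (16, 0): "PA",   # palmitic
    (18, 0): "SA",   # stearic
    (18, 1): "OA",   # oleic
    (18, 2): "LA",   # linoleic
    (20, 4): "AA",   # arachidonic
    (22, 6): "DHA",  # docosahexaenoic
    (22, 0): "BA",   # behenic
    (24, 0): "LGA",  # lignoceric
    (24, 1): "NA",   # nervonic
}


def _cis(*positions: int) -> tuple[tuple[int, str], ...]:
    return tuple((p, "cis") for p in positions)


# ---------------------------------------------------------------- chains
PA16 = ChainSpec(16)
SA18 = ChainSpec(18)
OA18 = ChainSpec(18, _cis(9))
LA18 = ChainSpec(18, _cis(9, 12))
AA20 = ChainSpec(20, _cis(5, 8, 11, 14))
DHA22 = ChainSpec(22, _cis(4, 7, 10, 13, 16, 19))
BA22 = ChainSpec(22)
LGA24 = ChainSpec(24)
NA24 = ChainSpec(24, _cis(15))

# Primary trans-cis hydroperoxide derivatives of LA, AA and DHA.
HPODE9 = ChainSpec(18, ((10, "trans"), (12, "cis")), (9,))
HPODE13 = ChainSpec(18, ((9, "cis"), (11, "trans")), (13,))
HPETE12 = ChainSpec(
    20, ((5, "cis"), (8, "cis"), (10, "trans"), (14, "cis")), (12,))
HPETE15 = ChainSpec(
    20, ((5, "cis"), (8, "cis"), (11, "cis"), (13, "trans")), (15,))
HPDHA14 = ChainSpec(
    22, ((4, "cis"), (7, "cis"), (10, "cis"), (12, "trans"),
         (16, "cis"), (19, "cis")), (14,))
HPDHA17 = ChainSpec(
    22, ((4, "cis"), (7, "cis"), (10, "cis"), (13, "cis"),
         (15, "trans"), (19, "cis")), (17,))

#: hydroperoxide isomers per PUFA class: position -> oxidized chain
HPD_ISOMERS: dict[str, dict[int, ChainSpec]] = {
    "LA": {9: HPODE9, 13: HPODE13},
    "AA": {12: HPETE12, 15: HPETE15},
    "DHA": {14: HPDHA14, 17: HPDHA17},
}

#: (lower, higher) oxidized-carbon positions per PUFA class
HPD_POSITIONS = {"LA": (9, 13), "AA": (12, 15), "DHA": (14, 17)}


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species: headgroup class plus sn-1/sn-2 chains.

    Cholesterol has no chains; sphingomyelins carry a sphingoid backbone
    (``sphingoid=True``) and a single N-acyl chain stored in ``sn2``.
    PS species carry formal charge -1.
    """

    name: str
    headgroup_class: str  # PC | PE | PS | SM | CHOL
    sn1: ChainSpec | None = None
    sn2: ChainSpec | None = None
    formal_charge: int = 0
    sphingoid: bool = False

    def __post_init__(self):
        if self.headgroup_class not in ("PC", "PE", "PS", "SM", "CHOL"):
            raise CompositionError(f"bad headgroup class {self.headgroup_class!r}")
        if self.headgroup_class == "CHOL" and (self.sn1 or self.sn2):
            raise CompositionError("cholesterol has no acyl chains")
        if self.headgroup_class == "SM" and not self.sphingoid:
            raise CompositionError("SM species must set the sphingoid flag")
        if self.headgroup_class == "PS" and self.formal_charge != -1:
            raise CompositionError("PS species carry charge -1")

    @property
    def chains(self) -> list[ChainSpec]:
        return [c for c in (self.sn1, self.sn2) if c is not None]

    @property
    def is_pufa(self) -> bool:
        return any(c.is_pufa for c in self.chains)

    @property
    def is_oxidized(self) -> bool:
        return any(c.is_oxidized for c in self.chains)

    @property
    def pufa_class(self) -> str | None:
        """LA/AA/DHA class of PUFA chains (all PUFA chains here share it)."""
        for c in self.chains:
            if c.is_pufa:
                return c.fatty_acid_class
        return None

    @property
    def n_pufa_chains(self) -> int:
        return sum(c.is_pufa for c in self.chains)


def _pl(name, hg, sn1, sn2):
    q = -1 if hg == "PS" else 0
    return LipidSpecies(name, hg, sn1, sn2, formal_charge=q)


def _sm(name, nacyl):
    return LipidSpecies(name, "SM", None, nacyl, sphingoid=True)


CHOLESTEROL = LipidSpecies("CHOL", "CHOL")

#: native (non-oxidized) species vocabulary
NATIVE_SPECIES: dict[str, LipidSpecies] = {s.name: s for s in [
    # PE
    _pl("PLPE", "PE", PA16, LA18),
    _pl("SLPE", "PE", SA18, LA18),
    _pl("DLPE", "PE", LA18, LA18),
    _pl("SAPE", "PE", SA18, AA20),
    _pl("DAPE", "PE", AA20, AA20),
    _pl("SDPE", "PE", SA18, DHA22),
    _pl("ODPE", "PE", OA18, DHA22),
    _pl("DDPE", "PE", DHA22, DHA22),
    _pl("POPE", "PE", PA16, OA18),
    _pl("DPPE", "PE", PA16, PA16),
    # PC
    _pl("PLPC", "PC", PA16, LA18),
    _pl("SLPC", "PC", SA18, LA18),
    _pl("OLPC", "PC", OA18, LA18),
    _pl("DLPC", "PC", LA18, LA18),
    _pl("SAPC", "PC", SA18, AA20),
    _pl("DAPC", "PC", AA20, AA20),
    _pl("SDPC", "PC", SA18, DHA22),
    _pl("POPC", "PC", PA16, OA18),
    _pl("DPPC", "PC", PA16, PA16),
    # PS
    _pl("SLPS", "PS", SA18, LA18),
    _pl("SAPS", "PS", SA18, AA20),
    _pl("DAPS", "PS", AA20, AA20),
    _pl("SDPS", "PS", SA18, DHA22),
    _pl("DDPS", "PS", DHA22, DHA22),
    _pl("DSPS", "PS", SA18, SA18),
    _pl("SOPS", "PS", SA18, OA18),
    # SM (single N-acyl chain on the sphingoid backbone)
    _sm("PSM", PA16),
    _sm("SSM", SA18),
    _sm("LNSM", LA18),
    _sm("LSM", LGA24),
    _sm("BSM", BA22),
    _sm("NSM", NA24),
    _sm("DSM", DHA22),
    # sterol
    CHOLESTEROL,
]}


def oxidized_species(base: LipidSpecies, sn1_pos: int | None,
                     sn2_pos: int | None) -> LipidSpecies:
    """Derive the hydroperoxidized variant of a PUFA-bearing species.

    ``sn1_pos``/``sn2_pos`` name the oxidized carbon of the respective
    chain (None leaves the chain untouched; for SM the single N-acyl
    chain is addressed through ``sn2_pos``).
    """
    cls = base.pufa_class
    if cls is None:
        raise CompositionError(f"{base.name} has no PUFA chain to oxidize")
    isomers = HPD_ISOMERS[cls]
    sn1, sn2 = base.sn1, base.sn2
    positions = []
    if sn1_pos is not None:
        if sn1 is None or not sn1.is_pufa:
            raise CompositionError(f"{base.name}: sn1 is not a PUFA chain")
        sn1 = isomers[sn1_pos]
        positions.append(sn1_pos)
    if sn2_pos is not None:
        if sn2 is None or not sn2.is_pufa:
            raise CompositionError(f"{base.name}: sn2 is not a PUFA chain")
        sn2 = isomers[sn2_pos]
        positions.append(sn2_pos)
    if sn1_pos is not None and sn2_pos is not None:
        # doubly oxidized species use the conventional "9,13" style name
        name = f"{base.name}{min(positions)},{max(positions)}"
    else:
        name = f"{base.name}{positions[0]}"
    return replace(base, name=name, sn1=sn1, sn2=sn2)


def all_species() -> dict[str, LipidSpecies]:
    """Native vocabulary plus every derivable hydroperoxidized variant."""
    out = dict(NATIVE_SPECIES)
    for sp in NATIVE_SPECIES.values():
        if not sp.is_pufa:
            continue
        lo, hi = HPD_POSITIONS[sp.pufa_class]
        if sp.n_pufa_chains == 2:
            v = oxidized_species(sp, hi, lo)
            out[v.name] = v
        else:
            for pos in (lo, hi):
                v = oxidized_species(sp, None, pos)
                out[v.name] = v
    return out


SPECIES: dict[str, LipidSpecies] = all_species()
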