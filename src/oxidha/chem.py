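"""Fatty-acid chains, oxygenated positional isomers, formulas and masses.

Docosahexaenoic acid (DHA, 22:6 n-3) carries six methylene-interrupted *Z*
double bonds at Δ4,7,10,13,16,19.  Singlet-oxygen (ene) or radical oxidation
attaches an -OOH (hydroperoxide) or, after reduction, an -OH (hydroxide) group
to one carbon of a double bond and shifts that bond by one position, with *E*
geometry, away from the oxygenated carbon:

* proximal attack (lower-numbered carbon ``n`` of Δn): Δn → Δ(n+1) *E*;
* distal attack (higher-numbered carbon ``n`` of Δ(n−1)): Δ(n−1) → Δ(n−2) *E*.

Applied to DHA this yields exactly twelve positional isomers of each of the
hydroperoxy (HpDoHE) and hydroxy (HDoHE) series, oxygenated at carbons
4, 5, 7, 8, 10, 11, 13, 14, 16, 17, 19 and 20.  The same rule reproduces the
literature double-bond layouts of 5-HETE and 12-HETE, which anchors it.

Carbon numbering is 1-based from the carboxyl carbon; a double-bond position
``d`` denotes the bond between C\\ ``d`` and C\\ ``d+1`` (Δ nomenclature).
Z/E geometry is carried for bookkeeping only — it never affects a mass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

# --------------------------------------------------------------------------
# Atomic constants (monoisotopic, Da).  Kept as named constants so the mass
# arithmetic is consistent bit-for-bit with the test oracles.
# --------------------------------------------------------------------------
MASS_C = 12.000000
MASS_H = 1.0078250319
MASS_O = 15.9949146
MASS_D = 2.0141018
MASS_ELECTRON = 0.0005486

ATOMIC_MASSES: Mapping[str, float] = {
    "C": MASS_C,
    "H": MASS_H,
    "O": MASS_O,
    "D": MASS_D,
}

OxyType = Literal["OH", "OOH"]
Species = Literal["neutral", "deprotonated_anion"]

#: Oxygenation positions that yield the twelve DHA positional isomers.
ISOMER_POSITIONS: tuple[int, ...] = (4, 5, 7, 8, 10, 11, 13, 14, 16, 17, 19, 20)

_HILL_ORDER = ("C", "H", "D", "O")


@dataclass(frozen=True)
class ChemicalFormula:
    """Elemental composition over C, H, O and D (deuterium labels).

    Supports addition/subtraction so fragment bookkeeping (hydrogen shifts,
    neutral losses) stays explicit.  Counts must be non-negative.
    """

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ChemicalFormula":
        for el, n in counts.items():
            if el not in ATOMIC_MASSES:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        items = tuple((el, int(counts[el])) for el in _HILL_ORDER if counts.get(el, 0))
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ChemicalFormula.from_dict(merged)

    def subtract(self, other: "ChemicalFormula") -> "ChemicalFormula":
        """Subtract; raises ValueError if any count would go negative."""
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(f"negative {el} count after subtraction")
        return ChemicalFormula.from_dict(merged)

    def try_subtract(self, other: "ChemicalFormula") -> "ChemicalFormula | None":
        try:
            return self.subtract(other)
        except ValueError:
            return None

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return sum(ATOMIC_MASSES[el] * n for el, n in self.counts)

    def __str__(self) -> str:
        parts = []
        for el, n in self.counts:
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts) or "∅"


# Common neutral-loss compositions.
WATER = ChemicalFormula.from_dict({"H": 2, "O": 1})
CO2 = ChemicalFormula.from_dict({"C": 1, "O": 2})
H_ATOM = ChemicalFormula.from_dict({"H": 1})


@dataclass(frozen=True)
class FattyAcidBackbone:
    """An unbranched fatty-acid chain.

    ``double_bonds`` is a set of ``(position, geometry)`` pairs where the
    position ``d`` means a C=C between carbons ``d`` and ``d+1`` and geometry
    is ``"Z"`` or ``"E"``.  ``isotope_labels`` counts deuterium substitutions
    (site-unspecific; only the d8 internal standards use it).
    """

    chain_length: int
    double_bonds: frozenset[tuple[int, str]]
    isotope_labels: int = 0

    def __post_init__(self) -> None:
        if self.chain_length < 2:
            raise ValueError("chain_length must be at least 2")
        positions = sorted(d for d, _ in self.double_bonds)
        for d, geom in self.double_bonds:
            if not 1 < d < self.chain_length:
                raise ValueError(f"double-bond position {d} outside chain")
            if geom not in ("Z", "E"):
                raise ValueError(f"bad geometry {geom!r}")
        for a, b in zip(positions, positions[1:]):
            if b - a < 2:
                raise ValueError(f"cumulated diene at Δ{a},Δ{b}")
        if self.isotope_labels < 0:
            raise ValueError("isotope_labels must be >= 0")

    @property
    def n_double_bonds(self) -> int:
        return len(self.double_bonds)

    def formula(self) -> ChemicalFormula:
        """Neutral free-acid composition C_n H_(2n-2u) O2 with D for labels."""
        n, u = self.chain_length, self.n_double_bonds
        h = 2 * n - 2 * u
        d = self.isotope_labels
        if d > h:
            raise ValueError("more deuterium labels than hydrogens")
        return ChemicalFormula.from_dict({"C": n, "H": h - d, "D": d, "O": 2})


def _bonds(*specs: str) -> frozenset[tuple[int, str]]:
    return frozenset((int(s[:-1]), s[-1]) for s in specs)


#: The DHA backbone: 22 carbons, all-Z Δ4,7,10,13,16,19.
DHA = FattyAcidBackbone(22, _bonds("4Z", "7Z", "10Z", "13Z", "16Z", "19Z"))

#: Arachidonate backbone of the HETE internal standards (20:4, all-Z Δ5,8,11,14).
ARACHIDONATE_D8 = FattyAcidBackbone(
    20, _bonds("5Z", "8Z", "11Z", "14Z"), isotope_labels=8
)


@dataclass(frozen=True)
class OxygenatedIsomer:
    """A fatty-acid chain oxygenated at one carbon, with shifted double bonds."""

    backbone: FattyAcidBackbone
    oxy_position: int
    oxy_type: OxyType
    rearranged_double_bonds: frozenset[tuple[int, str]]

    @property
    def chain_length(self) -> int:
        return self.backbone.chain_length

    @property
    def oxygen_added(self) -> int:
        return 1 if self.oxy_type == "OH" else 2

    @property
    def name(self) -> str:
        series = "HDoHE" if self.oxy_type == "OH" else "HpDoHE"
        return f"{self.oxy_position}-{series}"

    def sp2_carbons(self) -> frozenset[int]:
        """Carbons that are part of a C=C in the rearranged layout."""
        out: set[int] = set()
        for d, _ in self.rearranged_double_bonds:
            out.update((d, d + 1))
        return frozenset(out)

    def double_bond_string(self) -> str:
        return ";".join(
            f"{d}{g}" for d, g in sorted(self.rearranged_double_bonds)
        )


def build_isomer(
    position: int,
    oxy_type: OxyType,
    backbone: FattyAcidBackbone = DHA,
) -> OxygenatedIsomer:
    """Oxygenate ``backbone`` at ``position`` and shift the attacked bond.

    ``position`` must be one of the two carbons of exactly one original double
    bond.  Proximal attack (position = d of Δd) moves the bond to Δ(d+1) *E*;
    distal attack (position = d+1) moves it to Δ(d−1) *E*.  All other bonds
    keep their position and geometry, so the bond count is conserved.
    """
    if oxy_type not in ("OH", "OOH"):
        raise ValueError(f"oxy_type must be 'OH' or 'OOH', got {oxy_type!r}")
    if not 1 <= position <= backbone.chain_length:
        raise ValueError(
            f"position {position} outside C1..C{backbone.chain_length}"
        )
    positions = {d for d, _ in backbone.double_bonds}
    proximal = position in positions
    distal = (position - 1) in positions
    if proximal and distal:
        raise ValueError(f"C{position} lies between conjugated double bonds")
    if not (proximal or distal):
        raise ValueError(
            f"C{position} is not a double-bond carbon of this backbone"
        )
    if proximal:
        old, new = position, position + 1
    else:
        old, new = position - 1, position - 2
    if not 1 < new < backbone.chain_length:
        raise ValueError(f"shifted bond Δ{new} falls outside the chain")
    bonds = {(d, g) for d, g in backbone.double_bonds if d != old}
    bonds.add((new, "E"))
    rearranged = frozenset(bonds)
    if len(rearranged) != backbone.n_double_bonds:
        raise ValueError("double-bond shift collides with an existing bond")
    # The frozenset constructor tolerates near-collisions; re-validate spacing.
    FattyAcidBackbone(backbone.chain_length, rearranged, backbone.isotope_labels)
    return OxygenatedIsomer(backbone, position, oxy_type, rearranged)


def molecular_formula(isomer: OxygenatedIsomer) -> ChemicalFormula:
    """Neutral composition: backbone acid plus one (OH) or two (OOH) oxygens.

    The substitution C–H → C–OH keeps the hydrogen count unchanged, so the
    DHA series gives C22H32O3 (HDoHE) and C22H32O4 (HpDoHE).
    """
    return isomer.backbone.formula() + ChemicalFormula.from_dict(
        {"O": isomer.oxygen_added}
    )


def monoisotopic_mz(formula: ChemicalFormula, species: Species = "neutral") -> float:
    """Monoisotopic m/z of the neutral molecule or its [M−H]⁻ anion.

    The anion mass subtracts one hydrogen atom and adds one electron mass
    (deprotonation removes H⁺, i.e. a hydrogen atom minus its electron).
    """
    if not formula.counts:
        raise ValueError("empty formula")
    m = formula.monoisotopic_mass
    if species == "neutral":
        return m
    if species == "deprotonated_anion":
        if formula["H"] < 1:
            raise ValueError("cannot deprotonate a hydrogen-free formula")
        return m - MASS_H + MASS_ELECTRON
    raise ValueError(f"unknown species {species!r}")


# --------------------------------------------------------------------------
# Isomer registry
# --------------------------------------------------------------------------

def all_isomers(oxy_type: OxyType | None = None) -> list[OxygenatedIsomer]:
    """The 12 HDoHE and/or 12 HpDoHE positional isomers of DHA."""
    types: Iterable[OxyType] = ("OH", "OOH") if oxy_type is None else (oxy_type,)
    return [build_isomer(p, t) for t in types for p in ISOMER_POSITIONS]


def isomer_from_name(name: str) -> OxygenatedIsomer:
    """Parse names like ``"17-HDoHE"`` or ``"4-HpDoHE"``."""
    try:
        pos_str, series = name.split("-", 1)
        position = int(pos_str)
    except ValueError as exc:
        raise ValueError(f"unparseable isomer name {name!r}") from exc
    if series == "HDoHE":
        oxy: OxyType = "OH"
    elif series == "HpDoHE":
        oxy = "OOH"
    else:
        raise ValueError(f"unknown series {series!r} in {name!r}")
    if position not in ISOMER_POSITIONS:
        raise ValueError(
            f"position {position} is not a DHA oxygenation site; "
            f"valid: {ISOMER_POSITIONS}"
        )
    return build_isomer(position, oxy)


def registry_frame() -> pd.DataFrame:
    """All 24 isomers as a table: name, layout, formula, masses."""
    rows = []
    for iso in all_isomers():
        f = molecular_formula(iso)
        rows.append(
            {
                "name": iso.name,
                "oxy_position": iso.oxy_position,
                "oxy_type": iso.oxy_type,
                "double_bonds": iso.double_bond_string(),
                "formula": str(f),
                "neutral_mass": round(monoisotopic_mz(f, "neutral"), 4),
                "mz_deprotonated": round(
                    monoisotopic_mz(f, "deprotonated_anion"), 4
                ),
            }
        )
    return pd.DataFrame(rows)


# Internal standards: structure models used only for their precursor masses.
def internal_standards() -> dict[str, OxygenatedIsomer]:
    """5(S)- and 12(S)-HETE-d8 modeled on the arachidonate-d8 backbone."""
    return {
        "5(S)-HETE-d8": build_isomer(5, "OH", ARACHIDONATE_D8),
        "12(S)-HETE-d8": build_isomer(12, "OH", ARACHIDONATE_D8),
    }
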