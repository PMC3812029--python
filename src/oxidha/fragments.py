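"""Theoretical negative-mode CID fragments of oxygenated fatty acids.

Charge-remote fragmentation of a deprotonated hydro(pero)xy fatty acid cleaves
a C–C bond either adjacent to the oxygenated carbon (α) or one bond further
out (β), on the carboxy or the methyl side.  Either resulting segment can
retain the charge, the cleavage may be accompanied by a transfer of one or two
hydrogens, and the charged segment may shed small neutrals (H2O from a
hydroxyl-bearing segment, CO2 from a carboxylate-bearing one).

Each product is named by the field's three-letter code: the Greek letter gives
the cleaved bond (α/β), the second letter the side of that bond relative to
the oxygenated carbon (c = carboxy, m = methyl), the third the charge-retaining
segment, with a suffix for hydrogen shifts and losses — e.g. ``[αcc+H−CO2]−``
is the carboxy segment of the α-cleavage on the carboxy side, plus one
hydrogen, having lost CO2.

Because these segments depend on where the oxygen sits, their masses pin down
the oxygenation position, unlike the peripheral ("non-specific") losses of
H2O/CO2 from the intact precursor, which all positional isomers share.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .chem import (
    CO2,
    MASS_ELECTRON,
    WATER,
    ChemicalFormula,
    OxygenatedIsomer,
    molecular_formula,
    monoisotopic_mz,
)

Kind = Literal["alpha", "beta"]
Side = Literal["carboxy", "methyl"]
PrecursorForm = Literal["[M-H]-", "[M-H-H2O]-"]

_GREEK = {"alpha": "α", "beta": "β"}
_GREEK_INV = {v: k for k, v in _GREEK.items()}

#: Default hydrogen-shift window: at most two hydrogens in or out.
DEFAULT_SHIFT_RANGE: tuple[int, int] = (-2, 2)
#: Default matching tolerance for unit-resolution quadrupole settings (Da).
DEFAULT_TOLERANCE = 0.5


@dataclass(frozen=True)
class CleavageSpec:
    """One (bond, charge, hydrogen shift, neutral losses) combination."""

    kind: Kind
    side: Side
    charged_segment: Side
    hydrogen_shift: int = 0
    losses: tuple[str, ...] = ()  # sorted multiset over {"CO2", "H2O"}

    def __post_init__(self) -> None:
        if abs(self.hydrogen_shift) > 2:
            raise ValueError("|hydrogen_shift| must be <= 2")
        if any(l not in ("H2O", "CO2") for l in self.losses):
            raise ValueError(f"unknown loss in {self.losses}")
        if tuple(sorted(self.losses)) != self.losses:
            raise ValueError("losses must be sorted")

    @property
    def modification_cost(self) -> int:
        """Ranking key: total rearrangement (|H shift| + number of losses)."""
        return abs(self.hydrogen_shift) + len(self.losses)


@dataclass(frozen=True)
class FragmentIon:
    """A labeled cleavage (or peripheral-loss) product ion."""

    label: str
    carbon_range: tuple[int, int]  # inclusive first..last chain carbon
    formula: ChemicalFormula
    mz: float
    cleavage: CleavageSpec | None  # None for peripheral-loss ions
    precursor_form: PrecursorForm
    specific: bool

    @property
    def modification_cost(self) -> int:
        if self.cleavage is not None:
            return self.cleavage.modification_cost
        # peripheral ions: count the neutral losses encoded in the label
        cost = 1 if "-CO2" in self.label else 0
        if "-2H2O" in self.label:
            cost += 2
        elif "-H2O" in self.label:
            cost += 1
        return cost


@dataclass(frozen=True)
class Annotation:
    """Candidate assignments for one observed m/z, best first."""

    observed_mz: float
    candidates: tuple[tuple[FragmentIon, float], ...]  # (ion, mass error Da)

    @property
    def best(self) -> FragmentIon | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def specificity(self) -> str:
        if not self.candidates:
            return "unmatched"
        return "specific" if self.best.specific else "non-specific"


# --------------------------------------------------------------------------
# Cleavage geometry
# --------------------------------------------------------------------------

def cleavage_bonds(
    isomer: OxygenatedIsomer,
) -> dict[tuple[Kind, Side], tuple[int, int]]:
    """The four cleavable bonds around the oxygenated carbon C\\ ``n``.

    α-carboxy = (n−1, n); α-methyl = (n, n+1); β-carboxy = (n−2, n−1);
    β-methyl = (n+1, n+2).  Bonds that would fall outside the chain are
    omitted (the DHA oxygenation sites 4..20 always keep all four).
    """
    n, L = isomer.oxy_position, isomer.chain_length
    candidates: dict[tuple[Kind, Side], tuple[int, int]] = {
        ("alpha", "carboxy"): (n - 1, n),
        ("alpha", "methyl"): (n, n + 1),
        ("beta", "carboxy"): (n - 2, n - 1),
        ("beta", "methyl"): (n + 1, n + 2),
    }
    return {
        key: (a, b)
        for key, (a, b) in candidates.items()
        if 1 <= a and b <= L
    }


def _hydroxyl_equivalents(isomer: OxygenatedIsomer, dehydrated: bool) -> int:
    """Water molecules the oxygenated site can still surrender."""
    base = 1 if isomer.oxy_type == "OH" else 2
    return max(base - (1 if dehydrated else 0), 0)


def segment_formula(
    isomer: OxygenatedIsomer,
    bond: tuple[int, int],
    segment: Side,
    precursor_form: PrecursorForm = "[M-H]-",
) -> ChemicalFormula:
    """Radical-segment composition before any hydrogen shift or loss.

    Hydrogens are assigned per carbon of the rearranged layout: C1 carries
    none (deprotonated carboxylate, 2 O), a double-bond carbon one, an
    interior sp3 carbon two, the terminal methyl three, and the oxygenated
    sp3 carbon one plus one per terminal O–H of its oxy group.  For the
    dehydrated precursor the water is assigned to the oxygenated site, which
    then keeps one fewer oxygen and no hydrogens.
    """
    if isomer.backbone.isotope_labels:
        raise NotImplementedError(
            "segment formulas are not defined for isotope-labeled chains"
        )
    a, b = bond
    if b != a + 1:
        raise ValueError(f"bond {bond} is not between adjacent carbons")
    L = isomer.chain_length
    if segment == "carboxy":
        first, last = 1, a
    elif segment == "methyl":
        first, last = b, L
    else:
        raise ValueError(f"unknown segment {segment!r}")
    dehydrated = precursor_form == "[M-H-H2O]-"
    sp2 = isomer.sp2_carbons()
    n_oxy = isomer.oxy_position

    carbons = last - first + 1
    hydrogens = 0
    oxygens = 0
    for c in range(first, last + 1):
        if c == 1:
            oxygens += 2  # deprotonated carboxylate, no H
        elif c == n_oxy:
            if dehydrated:
                oxygens += isomer.oxygen_added - 1
                # carbonyl-like site: no C-H, no O-H left
            else:
                oxygens += isomer.oxygen_added
                hydrogens += 2  # one on carbon + one terminal O-H
        elif c == L:
            hydrogens += 3
        elif c in sp2:
            hydrogens += 1
        else:
            hydrogens += 2
    return ChemicalFormula.from_dict({"C": carbons, "H": hydrogens, "O": oxygens})


# --------------------------------------------------------------------------
# Nomenclature
# --------------------------------------------------------------------------

def fragment_label(cleavage: CleavageSpec) -> str:
    """Render the three-letter code plus shift/loss suffix, e.g. ``[βcm+H−H2O]−``.

    ASCII hyphens are used for the minus signs so labels survive CSV
    round-trips; the Greek letter and trailing charge mark match the field's
    notation.
    """
    head = _GREEK[cleavage.kind] + cleavage.side[0] + cleavage.charged_segment[0]
    s = cleavage.hydrogen_shift
    if s:
        sign = "+" if s > 0 else "-"
        mag = "" if abs(s) == 1 else str(abs(s))
        head += f"{sign}{mag}H"
    for loss, count in (
        ("H2O", cleavage.losses.count("H2O")),
        ("CO2", cleavage.losses.count("CO2")),
    ):
        if count == 1:
            head += f"-{loss}"
        elif count > 1:
            head += f"-{count}{loss}"
    return f"[{head}]-"


_LABEL_RE = re.compile(
    r"^\[([αβ])([cm])([cm])"
    r"(?:([+-])(2?)H)?"
    r"((?:-\d?(?:H2O|CO2))*)\]-$"
)


def parse_label(label: str) -> CleavageSpec:
    """Inverse of :func:`fragment_label` (raises ValueError on bad input)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"unparseable fragment label {label!r}")
    greek, side_c, charged_c, sign, two, loss_str = m.groups()
    side = {"c": "carboxy", "m": "methyl"}[side_c]
    charged = {"c": "carboxy", "m": "methyl"}[charged_c]
    shift = 0
    if sign:
        shift = (2 if two else 1) * (1 if sign == "+" else -1)
    losses: list[str] = []
    for count, name in re.findall(r"-(\d?)(H2O|CO2)", loss_str):
        losses.extend([name] * (int(count) if count else 1))
    return CleavageSpec(
        _GREEK_INV[greek], side, charged, shift, tuple(sorted(losses))
    )


# --------------------------------------------------------------------------
# Enumeration
# --------------------------------------------------------------------------

def precursor_anion_formula(
    isomer: OxygenatedIsomer, precursor_form: PrecursorForm = "[M-H]-"
) -> ChemicalFormula:
    """Composition of the selected precursor anion (charge carried implicitly)."""
    f = molecular_formula(isomer).subtract(ChemicalFormula.from_dict({"H": 1}))
    if precursor_form == "[M-H-H2O]-":
        f = f.subtract(WATER)
    return f


def precursor_mz(
    isomer: OxygenatedIsomer, precursor_form: PrecursorForm = "[M-H]-"
) -> float:
    return precursor_anion_formula(isomer, precursor_form).monoisotopic_mass + (
        MASS_ELECTRON
    )


def _anion_mz(formula: ChemicalFormula) -> float:
    return formula.monoisotopic_mass + MASS_ELECTRON


def _peripheral_series(
    isomer: OxygenatedIsomer,
) -> list[FragmentIon]:
    """Losses of H2O and/or CO2 from the intact [M−H]− — shared by all isomers."""
    base = precursor_anion_formula(isomer, "[M-H]-")
    max_h2o = 2 if isomer.oxy_type == "OOH" else 1
    out: list[FragmentIon] = []
    for n_h2o in range(0, max_h2o + 1):
        for n_co2 in range(0, 2):
            if n_h2o == n_co2 == 0:
                continue
            f = base
            ok = True
            for _ in range(n_h2o):
                nxt = f.try_subtract(WATER)
                if nxt is None:
                    ok = False
                    break
                f = nxt
            if ok and n_co2:
                nxt = f.try_subtract(CO2)
                ok = nxt is not None
                if ok:
                    f = nxt
            if not ok:
                continue
            label = "[M-H"
            if n_h2o:
                label += "-H2O" if n_h2o == 1 else f"-{n_h2o}H2O"
            if n_co2:
                label += "-CO2"
            label += "]-"
            out.append(
                FragmentIon(
                    label=label,
                    carbon_range=(1, isomer.chain_length),
                    formula=f,
                    mz=_anion_mz(f),
                    cleavage=None,
                    precursor_form="[M-H]-",
                    specific=False,
                )
            )
    return out


def enumerate_fragments(
    isomer: OxygenatedIsomer,
    precursor_form: PrecursorForm = "[M-H]-",
    shift_range: tuple[int, int] = DEFAULT_SHIFT_RANGE,
    max_co2: int = 1,
    include_peripheral: bool = True,
) -> list[FragmentIon]:
    """All admissible α/β cleavage ions (plus the peripheral-loss series).

    The Cartesian product runs over the four cleavable bonds, both
    charge-retaining segments, hydrogen shifts in ``shift_range`` and neutral
    losses: up to ``max_co2`` CO2 when the charged segment holds C1, and up
    to as many H2O as the segment has hydroxyl equivalents (1 for OH, 2 for
    OOH, one fewer from a dehydrated precursor, 0 when the oxygenated carbon
    sits in the other segment).  Duplicated compositions keep the
    lowest-rearrangement representative.  Every ion is lighter than its
    precursor.
    """
    dehydrated = precursor_form == "[M-H-H2O]-"
    prec_mz = precursor_mz(isomer, precursor_form)
    bonds = cleavage_bonds(isomer)
    lo, hi = shift_range
    ions: list[FragmentIon] = []
    for (kind, side), bond in bonds.items():
        for charged in ("carboxy", "methyl"):
            radical = segment_formula(isomer, bond, charged, precursor_form)
            first, last = (
                (1, bond[0]) if charged == "carboxy" else (bond[1], isomer.chain_length)
            )
            contains_c1 = charged == "carboxy"
            contains_oxy = first <= isomer.oxy_position <= last
            n_h2o_max = (
                _hydroxyl_equivalents(isomer, dehydrated) if contains_oxy else 0
            )
            n_co2_max = max_co2 if contains_c1 else 0
            for shift, n_h2o, n_co2 in itertools.product(
                range(lo, hi + 1),
                range(n_h2o_max + 1),
                range(n_co2_max + 1),
            ):
                f: ChemicalFormula | None = radical
                if shift >= 0:
                    f = f + ChemicalFormula.from_dict({"H": shift})
                else:
                    f = f.try_subtract(ChemicalFormula.from_dict({"H": -shift}))
                for _ in range(n_h2o):
                    if f is None:
                        break
                    f = f.try_subtract(WATER)
                if f is not None and n_co2:
                    f = f.try_subtract(CO2)
                if f is None or f["C"] < 1:
                    continue
                mz = _anion_mz(f)
                if mz >= prec_mz:
                    continue
                spec = CleavageSpec(
                    kind,
                    side,
                    charged,
                    shift,
                    tuple(sorted(["H2O"] * n_h2o + ["CO2"] * n_co2)),
                )
                ions.append(
                    FragmentIon(
                        label=fragment_label(spec),
                        carbon_range=(first, last),
                        formula=f,
                        mz=mz,
                        cleavage=spec,
                        precursor_form=precursor_form,
                        specific=True,
                    )
                )
    if include_peripheral and not dehydrated:
        ions.extend(_peripheral_series(isomer))
    # Deduplicate by composition, keeping the minimal-rearrangement assignment.
    best: dict[tuple, FragmentIon] = {}
    for ion in ions:
        key = ion.formula.counts
        kept = best.get(key)
        if kept is None or ion.modification_cost < kept.modification_cost:
            best[key] = ion
    return sorted(best.values(), key=lambda i: (i.mz, i.label))


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------

def match_peaks(
    isomer: OxygenatedIsomer,
    observed: Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
    precursor_form: PrecursorForm = "[M-H]-",
    fragments: Sequence[FragmentIon] | None = None,
) -> list[Annotation]:
    """Annotate observed m/z values against the enumerated fragments.

    Candidates within ``tolerance`` are ranked by modification cost (|H
    shift| + number of losses), ties by absolute mass error.  An observed
    value matching the precursor itself is annotated as the unfragmented
    precursor; peaks with no candidate come back with an empty list.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if fragments is None:
        fragments = enumerate_fragments(isomer, precursor_form)
    prec_mz = precursor_mz(isomer, precursor_form)
    prec_ion = FragmentIon(
        label=f"{precursor_form} (unfragmented precursor)",
        carbon_range=(1, isomer.chain_length),
        formula=precursor_anion_formula(isomer, precursor_form),
        mz=prec_mz,
        cleavage=None,
        precursor_form=precursor_form,
        specific=False,
    )
    annotations: list[Annotation] = []
    for obs in observed:
        cands: list[tuple[FragmentIon, float]] = []
        if abs(obs - prec_mz) <= tolerance:
            cands.append((prec_ion, obs - prec_mz))
        for ion in fragments:
            err = obs - ion.mz
            if abs(err) <= tolerance:
                cands.append((ion, err))
        cands.sort(key=lambda ce: (ce[0].modification_cost, abs(ce[1])))
        annotations.append(Annotation(obs, tuple(cands)))
    return annotations


def annotation_frame(
    isomer: OxygenatedIsomer, annotations: Iterable[Annotation]
) -> pd.DataFrame:
    """Flatten annotations into the report table (one row per observed m/z)."""
    rows = []
    for ann in annotations:
        if ann.best is None:
            rows.append(
                {
                    "observed_mz": ann.observed_mz,
                    "isomer": isomer.name,
                    "best_label": "unassigned",
                    "best_formula": "",
                    "theoretical_mz": float("nan"),
                    "error_da": float("nan"),
                    "rank": 0,
                    "specificity": "unmatched",
                }
            )
            continue
        ion, err = ann.candidates[0]
        rows.append(
            {
                "observed_mz": ann.observed_mz,
                "isomer": isomer.name,
                "best_label": ion.label,
                "best_formula": str(ion.formula),
                "theoretical_mz": round(ion.mz, 4),
                "error_da": round(err, 4),
                "rank": 1,
                "specificity": ann.specificity,
            }
        )
    return pd.DataFrame(rows)


def fragment_frame(
    isomer: OxygenatedIsomer, fragments: Iterable[FragmentIon]
) -> pd.DataFrame:
    """Enumerated-fragment table used by the predict-fragments command."""
    rows = [
        {
            "isomer": isomer.name,
            "label": ion.label,
            "first_carbon": ion.carbon_range[0],
            "last_carbon": ion.carbon_range[1],
            "formula": str(ion.formula),
            "mz": round(ion.mz, 4),
            "precursor_form": ion.precursor_form,
            "specificity": "specific" if ion.specific else "non-specific",
        }
        for ion in fragments
    ]
    return pd.DataFrame(rows)
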