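"""SRM acquisition methods for the HpDoHE and HDoHE isomer panels.

A selected-reaction-monitoring (SRM) method is a list of precursor→product
transitions acquired on a triple quadrupole.  Each analyte carries exactly two
transitions — one *quantitative* (used for the calibration and concentration
readout) and one *qualitative* (identity confirmation: the analyte is only
quantified when both co-elute) — plus two deuterated internal-standard
transitions.  The two reference methods packaged here are the optimized
instrument settings for the twelve hydroperoxy-DHA and twelve hydroxy-DHA
positional isomers; hydroperoxides and hydroxides are acquired in separate
methods so each chromatographic peak keeps ~15 data points.

Hydroperoxides dehydrate readily in the source, so several HpDoHE rows select
the [M−H−H2O]− ion at nominal m/z 341 instead of [M−H]− at 359; the stored
per-row precursor values (341.10/.20/.30, 359.10/.20/.30) are instrument
settings as printed, not chemically distinct species.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from . import fragments as frag
from .chem import isomer_from_name

AnalyteClass = Literal["HpDoHE", "HDoHE"]
Role = Literal["quantitative", "qualitative", "internal_standard"]

#: Fixed CSV column order for transition lists.
TRANSITION_COLUMNS = (
    "analyte_id",
    "class",
    "precursor_mz",
    "product_mz",
    "role",
    "cone_voltage",
    "collision_energy",
    "expected_rt_min",
    "peak_group",
)

INTERNAL_STANDARDS = ("5(S)-HETE-d8", "12(S)-HETE-d8")

#: Monitored span of the chromatographic run (min); printed analyte RTs fall
#: between 5.95 and 8.84 min.
GRADIENT_SPAN = (0.0, 10.0)

DWELL_TIME_MS = 9.0


@dataclass(frozen=True)
class SRMTransition:
    analyte_id: str
    precursor_mz: float
    product_mz: float
    role: Role
    cone_voltage: float
    collision_energy: float
    expected_rt: float
    peak_group: int | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("quantitative", "qualitative", "internal_standard"):
            raise ValueError(f"unknown role {self.role!r}")
        if not self.product_mz < self.precursor_mz:
            raise ValueError(
                f"{self.analyte_id}: product m/z {self.product_mz} not below "
                f"precursor {self.precursor_mz}"
            )
        if self.expected_rt <= 0:
            raise ValueError("expected_rt must be positive")

    @property
    def key(self) -> tuple[str, float, float]:
        return (self.analyte_id, self.precursor_mz, self.product_mz)


@dataclass(frozen=True)
class SRMMethod:
    name: str
    analyte_class: AnalyteClass
    transitions: tuple[SRMTransition, ...]
    polarity: str = "negative"
    dwell_time_ms: float = DWELL_TIME_MS

    @property
    def analytes(self) -> list[str]:
        """Non-IS analytes in method order (unique, order preserved)."""
        seen: dict[str, None] = {}
        for t in self.transitions:
            if t.role != "internal_standard":
                seen.setdefault(t.analyte_id, None)
        return list(seen)

    def transitions_for(self, analyte_id: str) -> list[SRMTransition]:
        return [t for t in self.transitions if t.analyte_id == analyte_id]

    def transition(self, analyte_id: str, role: Role) -> SRMTransition:
        for t in self.transitions:
            if t.analyte_id == analyte_id and t.role == role:
                return t
        raise KeyError(f"no {role} transition for {analyte_id}")


# --------------------------------------------------------------------------
# Reference methods (printed instrument settings)
# --------------------------------------------------------------------------
# Row layout: analyte, peak group, quant (precursor, product, CV, CE),
#             qual (precursor, product, CV, CE), RT.
_HPDOHE_ROWS = (
    ("20-HpDoHE", 2, (359.10, 71.10, 33, 14), (341.10, 71.10, 33, 14), 6.79),
    ("19-HpDoHE", 1, (341.30, 83.10, 41, 19), (359.30, 83.10, 41, 19), 6.66),
    ("17-HpDoHE", 4, (341.30, 111.20, 30, 12), (359.30, 111.20, 30, 12), 7.03),
    ("16-HpDoHE", 3, (341.20, 233.20, 31, 11), (359.20, 233.20, 31, 11), 7.11),
    ("14-HpDoHE", 6, (341.10, 151.10, 29, 11), (359.10, 151.10, 29, 11), 7.28),
    ("13-HpDoHE", 5, (341.10, 121.10, 32, 16), (359.10, 121.10, 32, 16), 7.22),
    ("11-HpDoHE", 7, (341.10, 243.20, 29, 11), (359.10, 243.20, 29, 11), 7.39),
    ("10-HpDoHE", 7, (341.10, 188.20, 31, 12), (359.10, 188.20, 31, 12), 7.39),
    ("8-HpDoHE", 8, (359.30, 108.30, 30, 16), (341.30, 113.10, 31, 9), 7.83),
    ("7-HpDoHE", 8, (341.10, 201.20, 25, 13), (359.10, 201.20, 25, 12), 7.80),
    ("5-HpDoHE", 9, (359.20, 281.30, 32, 10), (359.20, 147.20, 32, 8), 8.73),
    ("4-HpDoHE", 10, (341.30, 115.10, 22, 15), (359.20, 115.10, 22, 15), 8.84),
)

_HDOHE_ROWS = (
    ("20-HDoHE", 12, (343.10, 241.10, 36, 15), (343.10, 285.10, 36, 13), 5.95),
    ("19-HDoHE", 11, (343.10, 229.10, 32, 15), (343.10, 273.30, 32, 14), 6.10),
    ("17-HDoHE", 14, (343.10, 201.10, 27, 14), (343.10, 245.30, 27, 14), 6.46),
    ("16-HDoHE", 13, (343.10, 233.20, 26, 13), (343.10, 261.10, 26, 13), 6.36),
    ("14-HDoHE", 16, (343.10, 161.20, 30, 12), (343.10, 205.10, 30, 15), 6.71),
    ("13-HDoHE", 15, (343.10, 193.20, 30, 12), (343.10, 221.10, 30, 13), 6.58),
    ("11-HDoHE", 18, (343.10, 149.20, 28, 13), (343.10, 165.10, 28, 13), 6.95),
    ("10-HDoHE", 17, (343.10, 153.10, 28, 13), (343.10, 181.10, 28, 15), 6.84),
    ("8-HDoHE", 19, (343.10, 189.20, 32, 12), (343.10, 113.10, 32, 13), 7.35),
    ("7-HDoHE", 19, (343.10, 141.10, 31, 15), (343.10, 109.10, 31, 13), 7.36),
    ("5-HDoHE", 20, (343.20, 85.10, 26, 10), (343.20, 93.10, 26, 10), 8.07),
    ("4-HDoHE", 21, (343.10, 101.10, 29, 13), (343.10, 115.10, 29, 16), 8.40),
)

# Internal standards: (name, precursor, product, CV, CE, RT); shared by both
# methods.
_IS_ROWS = (
    ("5(S)-HETE-d8", 327.20, 116.10, 22, 14, 7.25),
    ("12(S)-HETE-d8", 327.20, 184.20, 30, 14, 6.13),
)

# Reported per-analyte validation figures: LOD (pg on column), r², calibrated
# range.  HpDoHE ranges in ng/µL, HDoHE ranges in pg/µL as printed.
_HPDOHE_PERFORMANCE = {
    "20-HpDoHE": (471.0, 0.998, "0.25-10"),
    "19-HpDoHE": (23.0, 0.992, "0.01-1"),
    "17-HpDoHE": (1.0, 0.991, "0.01-1"),
    "16-HpDoHE": (49.0, 0.99, "0.01-1"),
    "14-HpDoHE": (29.0, 0.991, "0.01-1"),
    "13-HpDoHE": (1.0, 0.996, "0.01-1"),
    "11-HpDoHE": (76.0, 0.998, "0.01-1"),
    "10-HpDoHE": (671.0, 0.983, "0.01-1"),
    "8-HpDoHE": (116.0, 0.995, "0.01-1"),
    "7-HpDoHE": (96.0, 0.997, "0.01-1"),
    "5-HpDoHE": (162.0, 0.981, "0.01-1"),
    "4-HpDoHE": (502.0, 0.999, "0.01-1"),
}

_HDOHE_PERFORMANCE = {
    "20-HDoHE": (2.71, 0.998, "0.62-100"),
    "19-HDoHE": (5.02, 0.999, "0.62-100"),
    "17-HDoHE": (3.89, 0.997, "1.25-100"),
    "16-HDoHE": (1.27, 0.996, "0.62-100"),
    "14-HDoHE": (2.60, 0.996, "0.25-100"),
    "13-HDoHE": (1.16, 0.997, "0.25-100"),
    "11-HDoHE": (5.30, 0.993, "0.25-100"),
    "10-HDoHE": (2.07, 0.998, "0.62-100"),
    "8-HDoHE": (1.63, 0.997, "0.25-100"),
    "7-HDoHE": (0.46, 0.994, "0.25-100"),
    "5-HDoHE": (8.48, 0.994, "1.25-100"),
    "4-HDoHE": (0.50, 0.994, "0.25-100"),
}


def reference_method(analyte_class: AnalyteClass) -> SRMMethod:
    """The packaged optimized method for one analyte class.

    12 analytes × (quantitative + qualitative) + 2 internal-standard
    transitions = 26 transitions, with printed cone voltages, collision
    energies, retention times and chromatographic peak-group numbers.
    """
    if analyte_class == "HpDoHE":
        rows = _HPDOHE_ROWS
    elif analyte_class == "HDoHE":
        rows = _HDOHE_ROWS
    else:
        raise ValueError(f"unknown analyte class {analyte_class!r}")
    transitions: list[SRMTransition] = []
    for name, peak, quant, qual, rt in rows:
        for role, (prec, prod, cv, ce) in (
            ("quantitative", quant),
            ("qualitative", qual),
        ):
            transitions.append(
                SRMTransition(name, prec, prod, role, cv, ce, rt, peak)
            )
    for name, prec, prod, cv, ce, rt in _IS_ROWS:
        transitions.append(
            SRMTransition(name, prec, prod, "internal_standard", cv, ce, rt)
        )
    return SRMMethod(
        name=f"{analyte_class} reference method",
        analyte_class=analyte_class,
        transitions=tuple(transitions),
    )


def reference_performance(analyte_class: AnalyteClass) -> pd.DataFrame:
    """Printed per-analyte LOD, r² and calibrated range for the reference method."""
    table = (
        _HPDOHE_PERFORMANCE if analyte_class == "HpDoHE" else _HDOHE_PERFORMANCE
    )
    unit = "ng/uL" if analyte_class == "HpDoHE" else "pg/uL"
    return pd.DataFrame(
        [
            {
                "analyte_id": name,
                "lod_pg": lod,
                "r_squared": r2,
                "calibrated_range": rng,
                "range_unit": unit,
            }
            for name, (lod, r2, rng) in table.items()
        ]
    )


# --------------------------------------------------------------------------
# Annotation & validation
# --------------------------------------------------------------------------

def _precursor_form_for(analyte_id: str, precursor_mz: float) -> frag.PrecursorForm:
    """Dehydrated precursors sit near nominal 341; intact anions near 343/359."""
    iso = isomer_from_name(analyte_id)
    mh = frag.precursor_mz(iso, "[M-H]-")
    mh_h2o = frag.precursor_mz(iso, "[M-H-H2O]-")
    return (
        "[M-H]-"
        if abs(precursor_mz - mh) <= abs(precursor_mz - mh_h2o)
        else "[M-H-H2O]-"
    )


def annotate_method(
    method: SRMMethod, tolerance: float = frag.DEFAULT_TOLERANCE
) -> SRMMethod:
    """Label each product ion with its best theoretical fragment assignment.

    Internal standards are not enumerated (their fragments involve the
    deuterated chain); analyte products with no candidate within tolerance
    are flagged ``unassigned`` rather than treated as errors.
    """
    cache: dict[tuple[str, str], list[frag.FragmentIon]] = {}
    annotated: list[SRMTransition] = []
    for t in method.transitions:
        if t.role == "internal_standard":
            annotated.append(
                replace(t, annotation="internal standard, not enumerated")
            )
            continue
        iso = isomer_from_name(t.analyte_id)
        form = _precursor_form_for(t.analyte_id, t.precursor_mz)
        key = (t.analyte_id, form)
        if key not in cache:
            cache[key] = frag.enumerate_fragments(iso, form)
        ann = frag.match_peaks(
            iso, [t.product_mz], tolerance, form, fragments=cache[key]
        )[0]
        label = ann.best.label if ann.best is not None else "unassigned"
        annotated.append(replace(t, annotation=label))
    return replace(method, transitions=tuple(annotated))


def validate_method(
    method: SRMMethod,
    rt_span: tuple[float, float] = GRADIENT_SPAN,
    rt_conflict_tol: float = 0.05,
) -> list[tuple[str, str]]:
    """Diagnostics as (severity, message); hard problems use severity 'error'.

    Hard conflicts: duplicate (analyte, precursor, product) triples, analytes
    missing one of the two roles, retention times outside the gradient span,
    and co-eluting analytes sharing an identical transition (indistinguishable
    signals).  Analytes that merely co-elute on different transitions — the
    10-/11-HpDoHE and 7-/8- pairs — get a soft note: they are separated by
    transition, not by retention time.
    """
    diags: list[tuple[str, str]] = []
    seen: dict[tuple, int] = {}
    for i, t in enumerate(method.transitions):
        if t.key in seen:
            diags.append(
                (
                    "error",
                    f"duplicate transition {t.key} (rows {seen[t.key]} and {i})",
                )
            )
        else:
            seen[t.key] = i
        if not rt_span[0] <= t.expected_rt <= rt_span[1]:
            diags.append(
                (
                    "error",
                    f"{t.analyte_id}: RT {t.expected_rt} outside gradient span "
                    f"{rt_span}",
                )
            )
    for analyte in method.analytes:
        roles = {t.role for t in method.transitions_for(analyte)}
        for role in ("quantitative", "qualitative"):
            if role not in roles:
                diags.append(
                    ("error", f"analyte {analyte} lacks {role} transition")
                )
    non_is = [t for t in method.transitions if t.role != "internal_standard"]
    for i, a in enumerate(non_is):
        for b in non_is[i + 1 :]:
            if a.analyte_id == b.analyte_id:
                continue
            if abs(a.expected_rt - b.expected_rt) > rt_conflict_tol:
                continue
            if (a.precursor_mz, a.product_mz) == (b.precursor_mz, b.product_mz):
                diags.append(
                    (
                        "error",
                        f"{a.analyte_id} and {b.analyte_id} co-elute on the "
                        f"same transition {a.precursor_mz}->{a.product_mz}",
                    )
                )
    noted: set[tuple[str, str]] = set()
    for i, a in enumerate(non_is):
        for b in non_is[i + 1 :]:
            pair = tuple(sorted({a.analyte_id, b.analyte_id}))
            if len(pair) < 2 or pair in noted:
                continue
            if abs(a.expected_rt - b.expected_rt) <= rt_conflict_tol:
                noted.add(pair)
                diags.append(
                    (
                        "note",
                        f"{pair[0]} and {pair[1]} co-elute "
                        f"(RT {a.expected_rt} / {b.expected_rt}); "
                        "disambiguated by transition",
                    )
                )
    return diags


# --------------------------------------------------------------------------
# CSV round-trip
# --------------------------------------------------------------------------

def method_frame(method: SRMMethod) -> pd.DataFrame:
    rows = []
    for t in method.transitions:
        rows.append(
            {
                "analyte_id": t.analyte_id,
                "class": method.analyte_class,
                "precursor_mz": f"{t.precursor_mz:.2f}",
                "product_mz": f"{t.product_mz:.2f}",
                "role": t.role,
                "cone_voltage": t.cone_voltage,
                "collision_energy": t.collision_energy,
                "expected_rt_min": f"{t.expected_rt:.2f}",
                "peak_group": "" if t.peak_group is None else t.peak_group,
            }
        )
    df = pd.DataFrame(rows, columns=list(TRANSITION_COLUMNS))
    if any(t.annotation is not None for t in method.transitions):
        df["annotation"] = [t.annotation or "" for t in method.transitions]
    return df


def write_transitions(method: SRMMethod, path: str | Path) -> None:
    """Write the transition list as diffable CSV (floats at 2 decimals)."""
    method_frame(method).to_csv(path, index=False)


def read_transitions(path: str | Path) -> SRMMethod:
    """Read a transition CSV back into an :class:`SRMMethod`.

    Malformed rows, unknown roles, non-numeric m/z and duplicated
    (analyte, precursor, product) triples raise ValueError with the
    offending row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    classes = sorted(set(df["class"]))
    if len(classes) != 1 or classes[0] not in ("HpDoHE", "HDoHE"):
        raise ValueError(f"expected a single analyte class, got {classes}")
    transitions: list[SRMTransition] = []
    seen: dict[tuple, int] = {}
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        try:
            prec = float(row["precursor_mz"])
            prod = float(row["product_mz"])
            rt = float(row["expected_rt_min"])
            cv = float(row["cone_voltage"])
            ce = float(row["collision_energy"])
        except ValueError as exc:
            raise ValueError(f"row {rownum}: non-numeric field ({exc})") from exc
        role = row["role"]
        if role not in ("quantitative", "qualitative", "internal_standard"):
            raise ValueError(f"row {rownum}: unknown role {role!r}")
        peak = row["peak_group"].strip()
        annotation = row.get("annotation", "") or None
        try:
            t = SRMTransition(
                row["analyte_id"],
                prec,
                prod,
                role,  # type: ignore[arg-type]
                cv,
                ce,
                rt,
                int(peak) if peak else None,
                annotation,
            )
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
        if t.key in seen:
            raise ValueError(
                f"row {rownum}: duplicate transition {t.key} "
                f"(first seen at row {seen[t.key]})"
            )
        seen[t.key] = rownum
        transitions.append(t)
    return SRMMethod(
        name=str(Path(path).stem),
        analyte_class=classes[0],  # type: ignore[arg-type]
        transitions=tuple(transitions),
    )
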