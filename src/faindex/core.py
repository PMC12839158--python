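"""Analyte panel metadata, sample I/O, and molar-percent conversion.

The pipeline starts at per-analyte plasma concentrations (ng/mL). Each
concentration is converted to a molar amount by dividing by the analyte's
molecular weight; a sample's composition is then expressed in molar percent
of the total over *quantified* analytes only. Analytes flagged below the
lower limit of quantification (LOQ) are excluded from the denominator and
carry no value in the output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union


class LipidClass(str, Enum):
    SFA = "SFA"
    MUFA = "MUFA"
    PUFA_N3 = "PUFA-n3"
    PUFA_N6 = "PUFA-n6"
    TRANS = "TRANS"
    OTHER = "OTHER"  # synthetic filler analytes, not part of the measured panel


class PanelMismatchError(ValueError):
    """A profile references an analyte not present in the panel."""


class EmptyProfileError(ValueError):
    """Every analyte in the profile is below LOQ; no molar total exists."""


class SchemaError(ValueError):
    """A cohort or panel file is missing a mandatory column."""


class CohortParseError(ValueError):
    """A cell failed to parse; carries row/column location in the message."""


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte of the measured panel.

    ``molecular_weight`` is the average molecular weight of the free
    (non-esterified) fatty acid in g/mol. ``loq`` is the lower limit of
    quantification in ng/mL, or None when unknown.
    """

    name: str
    lipid_class: LipidClass
    molecular_weight: float
    loq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"molecular_weight must be > 0 for {self.name!r}")
        if self.loq is not None and self.loq < 0:
            raise ValueError(f"loq must be >= 0 for {self.name!r}")


# Canonical analyte shorthands used throughout the package.
C18_0 = "C18:0"
C18_1N9 = "C18:1n-9"
DGLA = "C20:3n-6"
AA = "C20:4n-6"
ADA = "C22:4n-6"
EPA = "C20:5n-3"
DPA = "C22:5n-3"
DHA = "C22:6n-3"

# Average molecular weights (g/mol) of the free fatty acids; trans isomers
# share the MW of the cis species. Overridable through a panel file.
_PANEL_ROWS: tuple[tuple[str, LipidClass, float], ...] = (
    ("C12:0", LipidClass.SFA, 200.32),
    ("C14:0", LipidClass.SFA, 228.37),
    ("C16:0", LipidClass.SFA, 256.42),
    ("C17:0", LipidClass.SFA, 270.45),
    (C18_0, LipidClass.SFA, 284.48),
    ("C20:0", LipidClass.SFA, 312.53),
    ("C22:0", LipidClass.SFA, 340.58),
    ("C24:0", LipidClass.SFA, 368.64),
    ("C16:1n-7", LipidClass.MUFA, 254.41),
    (C18_1N9, LipidClass.MUFA, 282.46),
    ("C20:1n-9", LipidClass.MUFA, 310.51),
    ("C24:1n-9", LipidClass.MUFA, 366.62),
    ("C16:1n-7t", LipidClass.TRANS, 254.41),
    ("C18:1n-9t", LipidClass.TRANS, 282.46),
    ("C18:2n-6t", LipidClass.TRANS, 280.45),
    ("C18:2n-6", LipidClass.PUFA_N6, 280.45),
    ("C18:3n-6", LipidClass.PUFA_N6, 278.43),
    ("C20:2n-6", LipidClass.PUFA_N6, 308.50),
    (DGLA, LipidClass.PUFA_N6, 306.48),
    (AA, LipidClass.PUFA_N6, 304.47),
    (ADA, LipidClass.PUFA_N6, 332.52),
    (EPA, LipidClass.PUFA_N3, 302.45),
    (DPA, LipidClass.PUFA_N3, 330.50),
    (DHA, LipidClass.PUFA_N3, 328.49),
)

DEFAULT_PANEL: tuple[AnalyteSpec, ...] = tuple(
    AnalyteSpec(name, cls, mw) for name, cls, mw in _PANEL_ROWS
)

#: Marker for a below-LOQ measurement inside a ConcentrationProfile.
BELOW_LOQ = None

#: Sentinel token accepted in cohort CSV cells (case-insensitive); an empty
#: cell is equivalent.
LOQ_SENTINEL = "<LOQ"


@dataclass
class ConcentrationProfile:
    """One sample's per-analyte concentrations in ng/mL.

    A value of ``None`` marks a below-LOQ measurement.
    """

    sample_id: str
    group: str
    concentrations: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.concentrations.items():
            if value is not None and value < 0:
                raise ValueError(
                    f"negative concentration for {name!r} in sample {self.sample_id!r}"
                )


@dataclass
class MolarProfile:
    """One sample's composition in molar percent over quantified analytes.

    Below-LOQ analytes are absent from ``mol_percent`` (never stored as 0).
    """

    sample_id: str
    group: str
    mol_percent: dict[str, float] = field(default_factory=dict)


def _panel_index(panel: Sequence[AnalyteSpec]) -> dict[str, AnalyteSpec]:
    index: dict[str, AnalyteSpec] = {}
    for spec in panel:
        if spec.name in index:
            raise ValueError(f"duplicate analyte {spec.name!r} in panel")
        index[spec.name] = spec
    return index


def to_molar_percent(
    profile: ConcentrationProfile, panel: Sequence[AnalyteSpec] = DEFAULT_PANEL
) -> MolarProfile:
    """Convert a concentration profile (ng/mL) to molar percent.

    mol%_i = (conc_i / MW_i) / sum_j(conc_j / MW_j) * 100, the sum running
    over quantified analytes only. A concentration below the panel LOQ is
    treated the same as an explicit below-LOQ marker.

    Raises
    ------
    PanelMismatchError
        If the profile contains an analyte not in the panel.
    EmptyProfileError
        If every analyte is below LOQ.
    """
    index = _panel_index(panel)
    moles: dict[str, float] = {}
    for name, conc in profile.concentrations.items():
        spec = index.get(name)
        if spec is None:
            raise PanelMismatchError(
                f"analyte {name!r} in sample {profile.sample_id!r} is not in the panel"
            )
        if conc is BELOW_LOQ:
            continue
        if spec.loq is not None and conc < spec.loq:
            continue
        moles[name] = conc / spec.molecular_weight
    total = sum(moles.values())
    if not moles or total <= 0:
        raise EmptyProfileError(
            f"sample {profile.sample_id!r} has no quantified analyte above LOQ"
        )
    mol_percent = {name: 100.0 * m / total for name, m in moles.items()}
    return MolarProfile(profile.sample_id, profile.group, mol_percent)


# ---------------------------------------------------------------------------
# Panel file I/O (TSV: name, lipid_class, molecular_weight, loq)
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ("name", "lipid_class", "molecular_weight", "loq")


def read_panel(path: Union[str, Path]) -> list[AnalyteSpec]:
    """Read an analyte panel from a TSV file."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for column in ("name", "lipid_class", "molecular_weight"):
            if column not in header:
                raise SchemaError(f"panel file {path} is missing column {column!r}")
        panel = []
        for row in reader:
            loq_cell = (row.get("loq") or "").strip()
            panel.append(
                AnalyteSpec(
                    name=row["name"].strip(),
                    lipid_class=LipidClass(row["lipid_class"].strip()),
                    molecular_weight=float(row["molecular_weight"]),
                    loq=float(loq_cell) if loq_cell else None,
                )
            )
    _panel_index(panel)  # enforce uniqueness
    return panel


def write_panel(panel: Sequence[AnalyteSpec], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_PANEL_COLUMNS)
        for spec in panel:
            writer.writerow(
                [
                    spec.name,
                    spec.lipid_class.value,
                    repr(spec.molecular_weight),
                    "" if spec.loq is None else repr(spec.loq),
                ]
            )


# ---------------------------------------------------------------------------
# Cohort CSV I/O (wide: sample_id, group, one column per analyte)
# ---------------------------------------------------------------------------

Units = Literal["ng_per_ml", "mol_percent"]


def _parse_cell(cell: str, row_number: int, column: str) -> Optional[float]:
    text = cell.strip()
    if text == "" or text.upper() == LOQ_SENTINEL.upper():
        return BELOW_LOQ
    try:
        return float(text)
    except ValueError:
        raise CohortParseError(
            f"non-numeric cell {cell!r} at row {row_number}, column {column!r}"
        ) from None


def read_cohort(
    path: Union[str, Path],
    units: Units = "ng_per_ml",
    panel: Sequence[AnalyteSpec] = DEFAULT_PANEL,
) -> list[ConcentrationProfile] | list[MolarProfile]:
    """Read a wide cohort CSV into profiles.

    An empty cell or the ``<LOQ`` sentinel marks a below-LOQ measurement.
    With ``units="mol_percent"``, below-LOQ analytes are simply absent from
    the returned :class:`MolarProfile` records.
    """
    path = Path(path)
    index = _panel_index(panel)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        for column in ("sample_id", "group"):
            if column not in header:
                raise SchemaError(f"cohort file {path} is missing column {column!r}")
        analyte_columns = [c for c in header if c not in ("sample_id", "group")]
        for column in analyte_columns:
            if column not in index:
                raise PanelMismatchError(
                    f"cohort column {column!r} is not an analyte of the panel"
                )
        records: list = []
        for row_number, row in enumerate(reader, start=2):
            values = {
                column: _parse_cell(row[column] or "", row_number, column)
                for column in analyte_columns
            }
            if units == "ng_per_ml":
                records.append(
                    ConcentrationProfile(row["sample_id"], row["group"], values)
                )
            else:
                quantified = {k: v for k, v in values.items() if v is not None}
                records.append(
                    MolarProfile(row["sample_id"], row["group"], quantified)
                )
    return records


def write_cohort(
    profiles: Iterable[Union[ConcentrationProfile, MolarProfile]],
    path: Union[str, Path],
    panel: Sequence[AnalyteSpec] = DEFAULT_PANEL,
) -> None:
    """Write profiles to the wide cohort CSV dialect.

    Below-LOQ / absent analytes are written as the ``<LOQ`` sentinel so that
    read-back round-trips exactly.
    """
    profiles = list(profiles)
    path = Path(path)
    columns = [spec.name for spec in panel]
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["sample_id", "group", *columns])
        for profile in profiles:
            values: Mapping[str, Optional[float]]
            if isinstance(profile, ConcentrationProfile):
                values = profile.concentrations
            else:
                values = profile.mol_percent
            row = [profile.sample_id, profile.group]
            for column in columns:
                value = values.get(column, BELOW_LOQ)
                row.append(LOQ_SENTINEL if value is None else repr(value))
            writer.writerow(row)
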