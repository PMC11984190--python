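"""CSV input/output for the annotation pipeline.

All artifacts are plain comma-separated UTF-8 with ``.`` decimals: the
aligned 4-D feature table, the CCS library, the repeating-units table, the
optional mass-only suspect list, and the annotated output table (written
with a file name forced to end in ``_FIN.csv``).

Column names in feature tables vary by vendor, so the mapping from CSV
headers to the core fields (m/z, retention time, drift time, CCS) is
explicit configuration — there is no header auto-detection.  Columns that
are not mapped and are not abundance columns are carried through verbatim
to the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem_core import Formula, FormulaError, adduct_mz, monoisotopic_mass, nominal_mass

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnMapping",
    "FeatureRecord",
    "CcsLibraryEntry",
    "RepeatingUnit",
    "SuspectEntry",
    "AnnotationRecord",
    "TableSchemaError",
    "TableRowError",
    "SAMPLE_ROLES",
    "read_feature_table",
    "read_ccs_library",
    "read_repeating_units",
    "write_repeating_units",
    "default_repeating_units",
    "read_suspect_list",
    "read_sample_roles",
    "write_sample_roles",
    "write_fin_table",
    "fin_path",
]

SAMPLE_ROLES = ("sample", "field_blank", "lab_blank", "standard", "analytical_blank")


class TableSchemaError(ValueError):
    """A required column is missing or the table layout is invalid."""


class TableRowError(ValueError):
    """A specific row failed validation; the message names the row index."""


@dataclass
class ColumnMapping:
    """Maps CSV headers to core feature fields.

    Optional entries point at a feature-id column, an observed M+1 isotope
    percentage column, and the three MS/MS evidence boolean columns that an
    external fragmentation workflow may supply.
    """

    mz: str = "mz"
    rt: str = "rt"
    dt: str = "dt"
    ccs: str = "ccs"
    feature_id: str | None = None
    m1_pct: str | None = None
    class_fragment: str | None = None
    pfas_fragment: str | None = None
    common_f_fragment: str | None = None

    def required(self) -> dict[str, str]:
        return {"mz": self.mz, "rt": self.rt, "dt": self.dt, "ccs": self.ccs}


@dataclass
class FeatureRecord:
    """One aligned 4-D feature with per-sample abundances."""

    feature_id: str
    mz: float
    rt: float
    dt: float
    ccs: float
    abundances: dict[str, float] = field(default_factory=dict)
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: m/z must be > 0")
        if self.rt < 0 or self.dt < 0:
            raise ValueError(f"feature {self.feature_id}: RT/DT must be >= 0")
        if self.ccs <= 0:
            raise ValueError(f"feature {self.feature_id}: CCS must be > 0")
        for sid, a in self.abundances.items():
            if a < 0:
                raise ValueError(f"feature {self.feature_id}: negative abundance in {sid}")

    def abundance(self, sample_id: str) -> float:
        return self.abundances.get(sample_id, 0.0)


@dataclass(frozen=True)
class CcsLibraryEntry:
    """One (compound, adduct) library row with adduct m/z and CCS."""

    name: str
    neutral_formula: Formula
    adduct_label: str
    adduct_mz: float
    ccs: float
    smiles: str = ""
    identifiers: str = ""

    def __post_init__(self) -> None:
        if self.adduct_mz <= 0:
            raise ValueError(f"library entry {self.name}: adduct m/z must be > 0")
        if self.ccs <= 0:
            raise ValueError(f"library entry {self.name}: CCS must be > 0")


@dataclass(frozen=True)
class RepeatingUnit:
    """A homologue repeat unit (label, formula, masses, on/off toggle)."""

    label: str
    formula: Formula
    exact_mass: float
    nominal_mass: int
    enabled: bool = False


@dataclass(frozen=True)
class SuspectEntry:
    """A CCS-free suspect-list row; matched by mass only."""

    name: str
    formula: Formula | None
    mz: float


@dataclass
class AnnotationRecord:
    """Per-feature evidence, best match, and confidence grade (FIN payload)."""

    feature_id: str
    series_id: int | None = None
    series_unit: str = ""
    n_in_series: int = 0
    rt_flag: bool = False
    dt_flag: bool = False
    match_name: str = ""
    match_formula: str = ""
    match_adduct: str = ""
    mass_error_da: float | None = None
    mass_error_ppm: float | None = None
    ccs_error_pct: float | None = None
    co2_loss_conflict: bool = False
    md_flag: bool = False
    mass_defect: float | None = None
    ecn: float | None = None
    md_over_ecn: float | None = None
    mz_over_ecn: float | None = None
    grade: str = "E"
    pcl: str = "5"


# ---------------------------------------------------------------------------
# readers

def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def _as_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableRowError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None


def read_feature_table(
    path,
    sample_roles: Mapping[str, str],
    columns: ColumnMapping | None = None,
) -> list[FeatureRecord]:
    """Read an aligned feature table into :class:`FeatureRecord` rows.

    ``sample_roles`` maps abundance column names to experimental roles
    (``sample``, ``field_blank``, ``lab_blank``, ``standard``,
    ``analytical_blank``); every key must exist as a CSV column.  Empty
    abundance cells mean "not detected" and become 0.0.
    """
    columns = columns or ColumnMapping()
    for sid, role in sample_roles.items():
        if role not in SAMPLE_ROLES:
            raise TableSchemaError(
                f"unknown sample role {role!r} for column {sid!r}; "
                f"expected one of {', '.join(SAMPLE_ROLES)}"
            )
    df = _read_csv(path)
    for key, col in columns.required().items():
        if col not in df.columns:
            raise TableSchemaError(f"missing required column {col!r} (field {key})")
    for sid in sample_roles:
        if sid not in df.columns:
            raise TableSchemaError(f"missing abundance column {sid!r}")
    if columns.feature_id is not None and columns.feature_id not in df.columns:
        raise TableSchemaError(f"missing feature-id column {columns.feature_id!r}")

    mapped = set(columns.required().values()) | set(sample_roles)
    if columns.feature_id:
        mapped.add(columns.feature_id)
    extra_cols = [c for c in df.columns if c not in mapped]

    records: list[FeatureRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        fid = (
            str(row_map[columns.feature_id])
            if columns.feature_id
            else f"F{i + 1}"
        )
        if fid in seen:
            raise TableRowError(f"row {i}: duplicate feature_id {fid!r}")
        seen.add(fid)
        abundances = {}
        for sid in sample_roles:
            cell = row_map[sid].strip()
            abundances[sid] = _as_float(cell, sid, i) if cell else 0.0
        try:
            rec = FeatureRecord(
                feature_id=fid,
                mz=_as_float(row_map[columns.mz], columns.mz, i),
                rt=_as_float(row_map[columns.rt], columns.rt, i),
                dt=_as_float(row_map[columns.dt], columns.dt, i),
                ccs=_as_float(row_map[columns.ccs], columns.ccs, i),
                abundances=abundances,
                extras={c: row_map[c] for c in extra_cols},
            )
        except ValueError as exc:
            if isinstance(exc, TableRowError):
                raise
            raise TableRowError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


_LIBRARY_COLUMNS = {"name": "name", "formula": "formula", "adduct_mz": "adduct_mz", "ccs": "ccs"}


def read_ccs_library(path) -> list[CcsLibraryEntry]:
    """Read a CCS library CSV (name, formula, adduct, adduct_mz, ccs, ...).

    The adduct column is optional; rows without one default to ``[M-H]-``
    (logged).  ``(name, adduct)`` pairs must be unique.
    """
    df = _read_csv(path)
    for col in _LIBRARY_COLUMNS.values():
        if col not in df.columns:
            raise TableSchemaError(f"missing required library column {col!r}")
    has_adduct = "adduct" in df.columns
    if not has_adduct:
        logger.info("library %s has no 'adduct' column; defaulting to [M-H]-", path)

    entries: list[CcsLibraryEntry] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        try:
            formula = Formula.parse(row["formula"])
        except FormulaError as exc:
            raise TableRowError(f"row {i}: {exc}") from None
        adduct = (row["adduct"].strip() if has_adduct else "") or "[M-H]-"
        mz = _as_float(row["adduct_mz"], "adduct_mz", int(i))
        ccs = _as_float(row["ccs"], "ccs", int(i))
        if mz <= 0 or ccs <= 0:
            raise TableRowError(f"row {i}: adduct_mz and ccs must be > 0")
        key = (row["name"], adduct)
        if key in seen:
            raise TableRowError(f"row {i}: duplicate (name, adduct) {key!r}")
        seen.add(key)
        entries.append(
            CcsLibraryEntry(
                name=row["name"],
                neutral_formula=formula,
                adduct_label=adduct,
                adduct_mz=mz,
                ccs=ccs,
                smiles=row.get("smiles", ""),
                identifiers=row.get("identifiers", ""),
            )
        )
    return entries


_DEFAULT_UNITS = (
    ("CF2", True),
    ("CF2CF2O", False),
    ("CH2CF2", False),
    ("CH2CHF", False),
    ("CH2CH2CF2CF2", False),
    ("CF2CFCl", False),
    ("CH2CH2CF2CFCl", False),
    ("OCF2CFCF3", False),
)


def make_repeating_unit(label: str, formula_text: str | None = None, enabled: bool = False) -> RepeatingUnit:
    formula = Formula.parse(formula_text or label)
    return RepeatingUnit(
        label=label,
        formula=formula,
        exact_mass=monoisotopic_mass(formula),
        nominal_mass=nominal_mass(formula),
        enabled=enabled,
    )


def default_repeating_units() -> list[RepeatingUnit]:
    """The built-in repeat-unit table; only CF2 enabled by default."""
    return [make_repeating_unit(label, enabled=en) for label, en in _DEFAULT_UNITS]


_TRUE = {"true", "yes", "1"}
_FALSE = {"false", "no", "0", ""}


def _as_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise TableRowError(f"row {row}: expected TRUE/FALSE in column {column!r}, got {value!r}")


def read_repeating_units(path) -> list[RepeatingUnit]:
    df = _read_csv(path)
    for col in ("label", "formula", "enabled"):
        if col not in df.columns:
            raise TableSchemaError(f"missing repeating-units column {col!r}")
    units = []
    for i, row in df.iterrows():
        units.append(
            make_repeating_unit(
                row["label"], row["formula"], _as_bool(row["enabled"], "enabled", int(i))
            )
        )
    return units


def write_repeating_units(units: Sequence[RepeatingUnit], path) -> None:
    pd.DataFrame(
        {
            "label": [u.label for u in units],
            "formula": [str(u.formula) for u in units],
            "enabled": ["TRUE" if u.enabled else "FALSE" for u in units],
        }
    ).to_csv(path, index=False)


def read_suspect_list(path, adduct_label: str = "[M-H]-") -> list[SuspectEntry]:
    """Read a formula/m/z-only suspect list; deduplicated by formula.

    Rows need a ``formula`` or an ``mz`` column (formula wins; the adduct
    m/z is computed for ``adduct_label``).
    """
    df = _read_csv(path)
    if "formula" not in df.columns and "mz" not in df.columns:
        raise TableSchemaError("suspect list needs a 'formula' or 'mz' column")
    out: list[SuspectEntry] = []
    seen_formulas: set[str] = set()
    for i, row in df.iterrows():
        name = row.get("name", "") or f"suspect-{i}"
        ftext = row.get("formula", "").strip() if "formula" in df.columns else ""
        if ftext:
            formula = Formula.parse(ftext)
            if str(formula) in seen_formulas:
                continue
            seen_formulas.add(str(formula))
            out.append(SuspectEntry(name, formula, adduct_mz(formula, adduct_label)))
        else:
            mz = _as_float(row["mz"], "mz", int(i))
            out.append(SuspectEntry(name, None, mz))
    return out


def read_sample_roles(path) -> dict[str, str]:
    df = _read_csv(path)
    for col in ("sample_id", "role"):
        if col not in df.columns:
            raise TableSchemaError(f"missing sample-roles column {col!r}")
    roles = {}
    for i, row in df.iterrows():
        if row["role"] not in SAMPLE_ROLES:
            raise TableRowError(f"row {i}: unknown role {row['role']!r}")
        roles[row["sample_id"]] = row["role"]
    return roles


def write_sample_roles(roles: Mapping[str, str], path) -> None:
    pd.DataFrame({"sample_id": list(roles), "role": list(roles.values())}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# FIN output

#: Columns appended to the carried-through input columns.
FIN_COLUMNS = (
    "Series_ID",
    "Series_Unit",
    "N_In_Series",
    "RT_Flag",
    "DT_Flag",
    "Match_Name",
    "Match_Formula",
    "Match_Adduct",
    "Mass_Error_Da",
    "Mass_Error_ppm",
    "CCS_Error_Pct",
    "CO2_Loss_Conflict",
    "MD_Flag",
    "Mass_Defect",
    "ECN",
    "MD_over_ECN",
    "mz_over_ECN",
    "Grade",
    "PCL",
)


def fin_path(path) -> Path:
    """Force the output file name to end in ``_FIN.csv``."""
    p = Path(path)
    name = p.name
    if name.endswith("_FIN.csv"):
        return p
    if name.endswith(".csv"):
        name = name[: -len(".csv")]
    return p.with_name(name + "_FIN.csv")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_fin_table(
    features: Sequence[FeatureRecord],
    annotations: Mapping[str, AnnotationRecord],
    series: Sequence | None,
    path,
    columns: ColumnMapping | None = None,
) -> Path:
    """Write the annotated output table.

    Input columns come first (feature id, core fields under their mapped
    names, abundance columns, carried-through extras), followed by the
    appended annotation columns.  Returns the actual path written (name
    forced to end ``_FIN.csv``).
    """
    columns = columns or ColumnMapping()
    known = {f.feature_id for f in features}
    for fid in annotations:
        if fid not in known:
            raise KeyError(f"annotation for unknown feature_id {fid!r}")

    id_col = columns.feature_id or "feature_id"
    sample_cols: list[str] = []
    extra_cols: list[str] = []
    for f in features:
        for sid in f.abundances:
            if sid not in sample_cols:
                sample_cols.append(sid)
        for c in f.extras:
            if c not in extra_cols:
                extra_cols.append(c)

    header = (
        [id_col, columns.mz, columns.rt, columns.dt, columns.ccs]
        + sample_cols
        + extra_cols
        + list(FIN_COLUMNS)
    )
    rows = []
    blank = AnnotationRecord(feature_id="")
    for f in features:
        ann = annotations.get(f.feature_id, blank)
        row = [
            f.feature_id,
            _fmt(f.mz),
            _fmt(f.rt),
            _fmt(f.dt),
            _fmt(f.ccs),
        ]
        row += [_fmt(f.abundances.get(sid, 0.0)) for sid in sample_cols]
        row += [f.extras.get(c, "") for c in extra_cols]
        row += [
            _fmt(ann.series_id),
            ann.series_unit,
            _fmt(ann.n_in_series),
            _fmt(ann.rt_flag),
            _fmt(ann.dt_flag),
            ann.match_name,
            ann.match_formula,
            ann.match_adduct,
            _fmt(ann.mass_error_da),
            _fmt(ann.mass_error_ppm),
            _fmt(ann.ccs_error_pct),
            _fmt(ann.co2_loss_conflict),
            _fmt(ann.md_flag),
            _fmt(ann.mass_defect),
            _fmt(ann.ecn),
            _fmt(ann.md_over_ecn),
            _fmt(ann.mz_over_ecn),
            ann.grade,
            ann.pcl,
        ]
        rows.append(row)

    out = fin_path(path)
    pd.DataFrame(rows, columns=header).to_csv(out, index=False)
    return out
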