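"""Cohort CSV schema, unit validation and report serialization.

Comma-delimited UTF-8 with dot decimal separator; one row per patient;
missing values encoded as empty cells.  Column names carry explicit unit
suffixes.  The fibrinogen column is canonically g/L; values > 30 are
interpreted as mg/dL and divided by 100 with a conversion warning unless an
explicit ``fibrinogen_unit`` cell overrides the heuristic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import CohortIOError, ValidationError
from .evaluation import ReportBundle
from .types import (
    ClinicalContext,
    CoagulationPanel,
    ExclusionFlag,
    Outcome,
    PatientRecord,
    VitalSet,
)

__all__ = ["COHORT_COLUMNS", "ReadReport", "read_cohort", "write_cohort", "write_report"]

#: Published cohort-file schema, in order.
COHORT_COLUMNS = [
    "patient_id",
    "assessment_day",
    "outcome",
    "platelet_count_1e9_per_L",
    "platelet_prior_24h_1e9_per_L",
    "pt_sec",
    "pt_reference_sec",
    "aptt_sec",
    "aptt_reference_sec",
    "d_dimer_ug_per_mL",
    "fdp_ug_per_mL",
    "fibrinogen_g_per_L",
    "fibrinogen_unit",
    "temperature_C",
    "heart_rate_per_min",
    "respiratory_rate_per_min",
    "wbc_1e9_per_L",
    "map_mmHg",
    "lactate_mmol_per_L",
    "underlying_disease",
    "bleeding",
    "organ_failure",
    "septic_shock",
    "dialysis",
    "ventilated",
    "sofa_score",
    "sirs_score",
    "icd9_codes",
    "exclusion_flags",
]

#: Fibrinogen values above this are taken to be mg/dL and divided by 100.
FIBRINOGEN_MG_DL_HEURISTIC = 30.0


@dataclass
class ReadReport:
    """Summary of a cohort read: row counts, conversions and warnings."""

    n_rows: int = 0
    n_records: int = 0
    n_converted: int = 0
    unknown_columns: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _fmt_float(value: Optional[float]) -> str:
    return "" if value is None else repr(float(value))


def _fmt_int(value: Optional[int]) -> str:
    return "" if value is None else str(int(value))


def _fmt_bool(value: Optional[bool]) -> str:
    if value is None:
        return ""
    return "true" if value else "false"


def _parse_float(cell: str, column: str, line: int) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        raise CohortIOError(f"line {line}: column {column!r}: not a number: {cell!r}")


def _parse_int(cell: str, column: str, line: int) -> Optional[int]:
    value = _parse_float(cell, column, line)
    if value is None:
        return None
    if value != int(value):
        raise CohortIOError(f"line {line}: column {column!r}: not an integer: {cell!r}")
    return int(value)


def _parse_bool(cell: str, column: str, line: int) -> Optional[bool]:
    cell = cell.strip().lower()
    if not cell:
        return None
    if cell in ("true", "1", "yes", "y"):
        return True
    if cell in ("false", "0", "no", "n"):
        return False
    raise CohortIOError(f"line {line}: column {column!r}: not a boolean: {cell!r}")


def read_cohort(
    path: Union[str, Path], strict_header: bool = True
) -> tuple[list[PatientRecord], ReadReport]:
    """Read a cohort CSV into typed records, applying unit conversions.

    Returns ``(records, read_report)``.  Unknown columns warn and are
    ignored (never silently dropped from the report); a missing required
    column or a duplicate patient id is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise CohortIOError(f"no such file: {path}")
    report = ReadReport()
    records: list[PatientRecord] = []
    seen_ids: set[str] = set()

    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CohortIOError(f"{path}: empty file, no header")
        header = list(reader.fieldnames)
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing and strict_header:
            raise CohortIOError(f"{path}: missing required columns: {missing}")
        unknown = [c for c in header if c not in COHORT_COLUMNS]
        if unknown:
            report.unknown_columns = unknown
            report.warnings.append(f"unknown columns ignored: {unknown}")

        for line, row in enumerate(reader, start=2):
            report.n_rows += 1
            pid = (row.get("patient_id") or "").strip()
            if not pid:
                raise CohortIOError(f"line {line}: empty patient_id")
            if pid in seen_ids:
                raise CohortIOError(f"line {line}: duplicate patient_id {pid!r}")
            seen_ids.add(pid)

            def f(col: str) -> Optional[float]:
                return _parse_float(row.get(col, ""), col, line)

            def b(col: str) -> Optional[bool]:
                return _parse_bool(row.get(col, ""), col, line)

            fibrinogen = f("fibrinogen_g_per_L")
            unit = (row.get("fibrinogen_unit") or "").strip().lower()
            if fibrinogen is not None:
                if unit in ("mg/dl", "mg_dl", "mgdl"):
                    fibrinogen /= 100.0
                    report.n_converted += 1
                elif unit in ("g/l", "g_l", "gl"):
                    pass
                elif unit:
                    raise CohortIOError(
                        f"line {line}: unknown fibrinogen unit {unit!r}"
                    )
                elif fibrinogen > FIBRINOGEN_MG_DL_HEURISTIC:
                    report.warnings.append(
                        f"line {line}: fibrinogen {fibrinogen} assumed mg/dL, "
                        f"stored {fibrinogen / 100.0} g/L"
                    )
                    fibrinogen /= 100.0
                    report.n_converted += 1

            try:
                panel = CoagulationPanel(
                    platelet_count=f("platelet_count_1e9_per_L"),
                    platelet_prior_24h=f("platelet_prior_24h_1e9_per_L"),
                    pt_seconds=f("pt_sec"),
                    pt_reference_seconds=f("pt_reference_sec"),
                    aptt_seconds=f("aptt_sec"),
                    aptt_reference_seconds=f("aptt_reference_sec"),
                    d_dimer=f("d_dimer_ug_per_mL"),
                    fdp=f("fdp_ug_per_mL"),
                    fibrinogen=fibrinogen,
                )
                vitals = VitalSet(
                    temperature=f("temperature_C"),
                    heart_rate=f("heart_rate_per_min"),
                    respiratory_rate=f("respiratory_rate_per_min"),
                    wbc=f("wbc_1e9_per_L"),
                    map_mmhg=f("map_mmHg"),
                    lactate=f("lactate_mmol_per_L"),
                )
                context = ClinicalContext(
                    underlying_disease=b("underlying_disease"),
                    bleeding=b("bleeding"),
                    organ_failure=b("organ_failure"),
                    septic_shock=b("septic_shock"),
                    dialysis=b("dialysis"),
                    ventilated=b("ventilated"),
                    sofa_score=_parse_int(row.get("sofa_score", ""), "sofa_score", line),
                    sirs_precomputed=_parse_int(
                        row.get("sirs_score", ""), "sirs_score", line
                    ),
                    assessment_day=_parse_int(
                        row.get("assessment_day", ""), "assessment_day", line
                    )
                    or 1,
                )
                codes = tuple(
                    c.strip()
                    for c in (row.get("icd9_codes") or "").split(";")
                    if c.strip()
                )
                flags = frozenset(
                    ExclusionFlag(c.strip())
                    for c in (row.get("exclusion_flags") or "").split(";")
                    if c.strip()
                )
                record = PatientRecord(
                    patient_id=pid,
                    panel=panel,
                    vitals=vitals,
                    context=context,
                    outcome=Outcome.parse(row.get("outcome", "")),
                    icd9_codes=codes,
                    exclusion_flags=flags,
                )
            except (ValidationError, ValueError) as exc:
                raise CohortIOError(f"line {line}: {exc}") from exc
            records.append(record)
            report.n_records += 1

    if report.n_rows == 0:
        report.warnings.append("header-only file: empty cohort")
    return records, report


def write_cohort(cohort: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    """Write a cohort CSV with deterministic column and row order.

    ``read_cohort(write_cohort(cohort))`` reproduces the cohort exactly:
    floats are written with full round-trip precision and fibrinogen carries
    an explicit g/L unit cell so the mg/dL heuristic never re-fires.
    """
    path = Path(path)
    try:
        handle = path.open("w", newline="", encoding="utf-8")
    except OSError as exc:
        raise CohortIOError(f"cannot write {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for r in cohort:
            p, v, c = r.panel, r.vitals, r.context
            writer.writerow(
                [
                    r.patient_id,
                    _fmt_int(c.assessment_day),
                    r.outcome.value,
                    _fmt_float(p.platelet_count),
                    _fmt_float(p.platelet_prior_24h),
                    _fmt_float(p.pt_seconds),
                    _fmt_float(p.pt_reference_seconds),
                    _fmt_float(p.aptt_seconds),
                    _fmt_float(p.aptt_reference_seconds),
                    _fmt_float(p.d_dimer),
                    _fmt_float(p.fdp),
                    _fmt_float(p.fibrinogen),
                    "g/L" if p.fibrinogen is not None else "",
                    _fmt_float(v.temperature),
                    _fmt_float(v.heart_rate),
                    _fmt_float(v.respiratory_rate),
                    _fmt_float(v.wbc),
                    _fmt_float(v.map_mmhg),
                    _fmt_float(v.lactate),
                    _fmt_bool(c.underlying_disease),
                    _fmt_bool(c.bleeding),
                    _fmt_bool(c.organ_failure),
                    _fmt_bool(c.septic_shock),
                    _fmt_bool(c.dialysis),
                    _fmt_bool(c.ventilated),
                    _fmt_int(c.sofa_score),
                    _fmt_int(c.sirs_precomputed),
                    ";".join(r.icd9_codes),
                    ";".join(sorted(f.value for f in r.exclusion_flags)),
                ]
            )


def write_report(
    bundle: ReportBundle,
    path: Union[str, Path],
    summary_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write the metrics grid as CSV (and optionally the plain-text summary).

    Output is deterministic: stable column order, rows in the canonical
    criterion order, no timestamps.
    """
    path = Path(path)
    frame = bundle.to_frame()
    try:
        frame.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise CohortIOError(f"cannot write {path}: {exc}") from exc
    if summary_path is not None:
        try:
            Path(summary_path).write_text(bundle.to_text(), encoding="utf-8")
        except OSError as exc:
            raise CohortIOError(f"cannot write {summary_path}: {exc}") from exc
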