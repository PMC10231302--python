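"""Cohort CSV reading/writing with validation, and report serialisation.

The canonical cohort table is long format: one row per eye (OD/OS), one
or two rows per patient.  Demographic and environmental fields repeat on
both rows of a patient; per-eye optics differ.  Units are as declared in
the header names (years, hours/day, dioptres, prism dioptres, mm/year).

Required columns: patient_id, age_years, onset_age_years,
parents_myopic, outdoors_h_per_day, nearwork_h_per_day, eye, ser_d,
ser_change_d_per_yr.  Optional: al_change_mm_per_yr, rpr_nasal_d,
rpr_temporal_d, near_phoria_pd, accom_error_d, clinician_1..k
(at_risk/low_risk), followup_ser_change_d_per_yr.

Validation reports every violation with a 1-based data-row number
(header = row 1).  Missing required columns hard-fail; optional gaps are
loaded as absent measurements and flagged only when a model needs them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .factors import Decision, EyeMeasurements, PatientRecord

REQUIRED_COLUMNS = (
    "patient_id",
    "age_years",
    "onset_age_years",
    "parents_myopic",
    "outdoors_h_per_day",
    "nearwork_h_per_day",
    "eye",
    "ser_d",
    "ser_change_d_per_yr",
)

OPTIONAL_EYE_COLUMNS = (
    "al_change_mm_per_yr",
    "rpr_nasal_d",
    "rpr_temporal_d",
    "near_phoria_pd",
    "accom_error_d",
)

_CLINICIAN_RE = re.compile(r"^clinician_(\d+)$")


class SchemaError(ValueError):
    """The file cannot be read at all (missing file / malformed header)."""


@dataclass
class ValidationReport:
    """Row-level errors (rejected) and warnings (loaded anyway)."""

    errors: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, row: int, msg: str) -> None:
        self.errors.append((row, msg))

    def warn(self, row: int, msg: str) -> None:
        self.warnings.append((row, msg))

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for row, msg in self.errors:
            lines.append(f"  row {row}: ERROR {msg}")
        for row, msg in self.warnings:
            lines.append(f"  row {row}: WARNING {msg}")
        return "\n".join(lines)


def _num(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    return float(value)


def _label(value) -> Optional[Decision]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    key = str(value).strip().lower().replace("-", "_")
    if key == "":
        return None
    if key == "at_risk":
        return Decision.AT_RISK
    if key == "low_risk":
        return Decision.LOW_RISK
    raise ValueError(f"label must be at_risk/low_risk, got {value!r}")


def read_cohort(path) -> tuple[list[PatientRecord], ValidationReport]:
    """Read a long-format cohort CSV into typed records plus a report."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "eye": str})
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    clinician_cols = sorted(
        (c for c in df.columns if _CLINICIAN_RE.match(c)),
        key=lambda c: int(_CLINICIAN_RE.match(c).group(1)),
    )
    has_followup = "followup_ser_change_d_per_yr" in df.columns

    report = ValidationReport()
    # 1-based data-row numbers: header is row 1, first data row is 2
    df = df.assign(_row=df.index + 2)

    records: list[PatientRecord] = []
    for pid, group in df.groupby("patient_id", sort=False):
        first_row = int(group["_row"].iloc[0])
        eyes: dict[str, EyeMeasurements] = {}
        bad_patient = False
        for _, row in group.iterrows():
            rn = int(row["_row"])
            side = str(row["eye"]).strip().upper()
            if side not in ("OD", "OS"):
                report.error(rn, f"{pid}: eye must be OD or OS, got {row['eye']!r}")
                continue
            if side in eyes:
                report.error(rn, f"{pid}: duplicate {side} row")
                continue
            try:
                ser = _num(row["ser_d"])
                if ser is None:
                    raise ValueError("ser_d is required")
                eyes[side] = EyeMeasurements(
                    ser_d=ser,
                    ser_change_d_per_yr=_num(row["ser_change_d_per_yr"]),
                    al_change_mm_per_yr=_num(row.get("al_change_mm_per_yr")),
                    rpr_nasal_d=_num(row.get("rpr_nasal_d")),
                    rpr_temporal_d=_num(row.get("rpr_temporal_d")),
                    near_phoria_pd=_num(row.get("near_phoria_pd")),
                    accom_error_d=_num(row.get("accom_error_d")),
                )
            except ValueError as exc:
                msg = str(exc)
                if "inclusion" in msg:
                    msg = f"{pid}: myopia inclusion SER <= -0.50 violated ({msg})"
                else:
                    msg = f"{pid}: {msg}"
                report.error(rn, msg)
        # demographic consistency across eye rows
        for col in (
            "age_years",
            "onset_age_years",
            "parents_myopic",
            "outdoors_h_per_day",
            "nearwork_h_per_day",
        ):
            if group[col].nunique(dropna=False) > 1:
                report.warn(
                    first_row,
                    f"{pid}: inconsistent {col} across eye rows; using first",
                )
        head = group.iloc[0]
        labels: Optional[tuple[Decision, ...]] = None
        if clinician_cols:
            parsed = []
            label_err = False
            for c in clinician_cols:
                try:
                    parsed.append(_label(head[c]))
                except ValueError as exc:
                    report.error(first_row, f"{pid}: {c}: {exc}")
                    label_err = True
            if label_err:
                bad_patient = True
            elif any(v is not None for v in parsed):
                if any(v is None for v in parsed):
                    report.warn(
                        first_row, f"{pid}: partially missing clinician labels"
                    )
                labels = tuple(v for v in parsed if v is not None)
        if not eyes:
            report.error(first_row, f"{pid}: no valid eye rows; record dropped")
            continue
        if bad_patient:
            continue
        try:
            records.append(
                PatientRecord(
                    patient_id=str(pid),
                    age_at_presentation_yr=float(head["age_years"]),
                    age_of_onset_yr=float(head["onset_age_years"]),
                    myopic_parents=int(head["parents_myopic"]),
                    outdoors_h_per_day=float(head["outdoors_h_per_day"]),
                    nearwork_h_per_day=float(head["nearwork_h_per_day"]),
                    right_eye=eyes.get("OD"),
                    left_eye=eyes.get("OS"),
                    clinician_labels=labels,
                    followup_ser_change_d_per_yr=(
                        _num(head["followup_ser_change_d_per_yr"])
                        if has_followup
                        else None
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            report.error(first_row, f"{pid}: {exc}; record dropped")
    return records, report


def _fmt(value: Optional[float], decimals: int) -> str:
    if value is None:
        return ""
    return f"{value:.{decimals}f}"


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records back to the long CSV schema.

    Dioptre-valued fields are written to 2 decimals, hours to 1 decimal,
    ages to 2 decimals; output is deterministic for a given record list.
    """
    n_clin = max(
        (len(r.clinician_labels) for r in records if r.clinician_labels),
        default=0,
    )
    any_followup = any(
        r.followup_ser_change_d_per_yr is not None for r in records
    )
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_EYE_COLUMNS)
    cols += [f"clinician_{k + 1}" for k in range(n_clin)]
    if any_followup:
        cols.append("followup_ser_change_d_per_yr")

    rows = []
    for rec in records:
        for side, eye in (("OD", rec.right_eye), ("OS", rec.left_eye)):
            if eye is None:
                continue
            row = {
                "patient_id": rec.patient_id,
                "age_years": _fmt(rec.age_at_presentation_yr, 2),
                "onset_age_years": _fmt(rec.age_of_onset_yr, 2),
                "parents_myopic": rec.myopic_parents,
                "outdoors_h_per_day": _fmt(rec.outdoors_h_per_day, 1),
                "nearwork_h_per_day": _fmt(rec.nearwork_h_per_day, 1),
                "eye": side,
                "ser_d": _fmt(eye.ser_d, 2),
                "ser_change_d_per_yr": _fmt(eye.ser_change_d_per_yr, 2),
                "al_change_mm_per_yr": _fmt(eye.al_change_mm_per_yr, 2),
                "rpr_nasal_d": _fmt(eye.rpr_nasal_d, 2),
                "rpr_temporal_d": _fmt(eye.rpr_temporal_d, 2),
                "near_phoria_pd": _fmt(eye.near_phoria_pd, 2),
                "accom_error_d": _fmt(eye.accom_error_d, 2),
            }
            if rec.clinician_labels:
                for k, lab in enumerate(rec.clinician_labels):
                    row[f"clinician_{k + 1}"] = lab.value
            if any_followup:
                row["followup_ser_change_d_per_yr"] = _fmt(
                    rec.followup_ser_change_d_per_yr, 2
                )
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def scores_frame(breakdowns, records=None) -> pd.DataFrame:
    """One row per patient x model: categories, contributions, total.

    If ``records`` is given (aligned by patient_id), clinician label and
    follow-up columns are passed through so downstream evaluation needs
    only the score file.
    """
    by_id = {}
    if records is not None:
        by_id = {r.patient_id: r for r in records}
    rows = []
    for bd in breakdowns:
        row = {
            "patient_id": bd.patient_id,
            "model": bd.model_name,
            "eye_used": bd.eye_used or "",
        }
        for fs in bd.factor_scores:
            row[f"cat_{fs.factor.value}"] = fs.category.name
            row[f"pts_{fs.factor.value}"] = fs.contribution
        row["total_score"] = bd.total_score
        row["classification"] = (
            bd.classification.value if bd.classification else ""
        )
        rec = by_id.get(bd.patient_id)
        if rec is not None:
            if rec.clinician_labels:
                for k, lab in enumerate(rec.clinician_labels):
                    row[f"clinician_{k + 1}"] = lab.value
            if rec.followup_ser_change_d_per_yr is not None:
                row["followup_ser_change_d_per_yr"] = round(
                    rec.followup_ser_change_d_per_yr, 4
                )
        rows.append(row)
    return pd.DataFrame(rows)
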