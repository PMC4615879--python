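"""Patient-level cohort schema, validation, and CSV round-tripping.

One :class:`PatientRecord` is one surgical admission: the procedure category,
basic demographics and comorbidity score, whether one or more in-hospital
postoperative complications occurred, total hospital cost (index stay plus
any 30-day readmission, USD), hospital length of stay, and the 30-day
readmission flag. Costs may be missing when the source system could not
produce a valid figure; the ``cost_valid`` flag tracks that explicitly so
downstream stages can restrict cost statistics to valid records while still
counting every patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical labels for the ten studied procedure categories.
PROCEDURES: tuple[str, ...] = (
    "AAA open repair",
    "vascular bypass",
    "esophagectomy",
    "gastrectomy",
    "colectomy",
    "resection of rectum",
    "hepatectomy",
    "pancreatectomy",
    "cystectomy",
    "F&H fracture repair",
)

_PROCEDURE_LOOKUP = {p.lower(): p for p in PROCEDURES}

GENDERS = ("female", "male")

#: CSV column order (fixed so writes are byte-stable).
COLUMNS = (
    "patient_id",
    "procedure",
    "age",
    "gender",
    "elective",
    "cci",
    "complication",
    "cost",
    "cost_valid",
    "los",
    "readmit_30d",
)


class SchemaError(ValueError):
    """The file's header does not match the cohort schema."""


class RecordValidationError(ValueError):
    """A row violates a record invariant; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


def canonical_procedure(label: str) -> str:
    """Map a procedure label to its canonical form.

    Matching is case-insensitive with surrounding whitespace stripped;
    anything else raises ``RecordValidationError``.
    """
    key = label.strip().lower()
    try:
        return _PROCEDURE_LOOKUP[key]
    except KeyError:
        raise RecordValidationError(f"unknown procedure label {label!r}") from None


@dataclass
class PatientRecord:
    """One surgical admission.

    ``cost`` is in whole US dollars and is present iff ``cost_valid`` is
    true. ``los`` is the index-stay length in whole days, at least 1.
    """

    patient_id: str
    procedure: str
    age: float
    gender: str
    elective: bool
    cci: int
    complication: bool
    cost: float | None
    cost_valid: bool
    los: int
    readmit_30d: bool

    def validate(self) -> None:
        """Raise ``RecordValidationError`` on any invariant violation."""
        self.procedure = canonical_procedure(self.procedure)
        if self.gender not in GENDERS:
            raise RecordValidationError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.age < 18:
            raise RecordValidationError(f"age {self.age} below 18 (adult cohort only)")
        if self.cci < 0 or int(self.cci) != self.cci:
            raise RecordValidationError(f"cci must be a non-negative integer, got {self.cci}")
        if self.cost_valid:
            if self.cost is None or pd.isna(self.cost):
                raise RecordValidationError("cost_valid is true but cost is missing")
            if self.cost < 0:
                raise RecordValidationError(f"cost must be non-negative, got {self.cost}")
        else:
            if self.cost is not None and not pd.isna(self.cost):
                raise RecordValidationError("cost_valid is false but cost is present")
            self.cost = None
        if self.los < 1 or int(self.los) != self.los:
            raise RecordValidationError(f"los must be an integer >= 1, got {self.los}")


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise RecordValidationError(f"column {column}: cannot parse boolean from {value!r}")


def read_cohort(path, strict: bool = True) -> list[PatientRecord]:
    """Read a patient-level cohort CSV.

    Parameters
    ----------
    path:
        CSV file with header; missing costs are empty cells.
    strict:
        If true, the first invalid row raises. If false, invalid rows are
        dropped and their count logged.

    Returns
    -------
    list of validated :class:`PatientRecord`.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "procedure": str, "gender": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            cost = getattr(row, "cost")
            rec = PatientRecord(
                patient_id=str(getattr(row, "patient_id")),
                procedure=str(getattr(row, "procedure")),
                age=float(getattr(row, "age")),
                gender=str(getattr(row, "gender")).strip().lower(),
                elective=_parse_bool(getattr(row, "elective"), "elective"),
                cci=int(getattr(row, "cci")),
                complication=_parse_bool(getattr(row, "complication"), "complication"),
                cost=None if pd.isna(cost) else float(cost),
                cost_valid=_parse_bool(getattr(row, "cost_valid"), "cost_valid"),
                los=int(getattr(row, "los")),
                readmit_30d=_parse_bool(getattr(row, "readmit_30d"), "readmit_30d"),
            )
            rec.validate()
        except (RecordValidationError, ValueError) as exc:
            if strict:
                if isinstance(exc, RecordValidationError) and exc.row is None:
                    raise RecordValidationError(str(exc), row=i) from None
                raise RecordValidationError(f"row {i}: {exc}") from None
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.warning("read_cohort: dropped %d invalid row(s) of %d", n_dropped, len(df))
    return records


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write records as CSV (fixed column order, empty cell for missing cost).

    ``read_cohort(write_cohort(x))`` reproduces ``x`` field for field.
    """
    rows = []
    for rec in records:
        rows.append({
            "patient_id": rec.patient_id,
            "procedure": rec.procedure,
            "age": f"{rec.age:g}",
            "gender": rec.gender,
            "elective": str(rec.elective).lower(),
            "cci": rec.cci,
            "complication": str(rec.complication).lower(),
            "cost": "" if rec.cost is None else f"{rec.cost:g}",
            "cost_valid": str(rec.cost_valid).lower(),
            "los": rec.los,
            "readmit_30d": str(rec.readmit_30d).lower(),
        })
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Columnar view of a cohort for vectorized summaries."""
    return pd.DataFrame({f.name: [getattr(r, f.name) for r in records]
                         for f in fields(PatientRecord)})
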