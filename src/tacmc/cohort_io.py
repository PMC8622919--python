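"""Longitudinal transplant-cohort data model and CSV round-trip.

A cohort is stored as two CSV tables sharing the ``patient_id`` key:

``patients.csv``
    patient_id, sex (M/F), age_years, cyp3a5 (*1/*1 | *1/*3 | *3/*3),
    acute_rejection (0/1), dgf (0/1, optional), formulation (TD/OD, optional)

``visits.csv``
    patient_id, time_months, c0_ng_ml, tdd_mg_day, creatinine_umol_l

Visits are variable-length per patient (typically 4-11 trough samples in
the 6-12 month window), which is why a long visits table is used instead
of one wide row per patient.  Optional fields are represented as absent
(``None`` / empty CSV cell), never as sentinel numerics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "VisitObservation",
    "PatientRecord",
    "Cohort",
    "ValidationIssue",
    "ValidationReport",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

SEXES = ("male", "female")
GENOTYPES = ("*1/*1", "*1/*3", "*3/*3")
FORMULATIONS = ("TD", "OD")

_SEX_TO_CSV = {"male": "M", "female": "F"}
_SEX_FROM_CSV = {"M": "male", "F": "female", "male": "male", "female": "female"}

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "age_years",
    "cyp3a5",
    "acute_rejection",
    "dgf",
    "formulation",
]
VISIT_COLUMNS = [
    "patient_id",
    "time_months",
    "c0_ng_ml",
    "tdd_mg_day",
    "creatinine_umol_l",
]

_REQUIRED_PATIENT_COLUMNS = ["patient_id", "sex", "age_years", "cyp3a5", "acute_rejection"]
_REQUIRED_VISIT_COLUMNS = ["patient_id", "time_months", "c0_ng_ml", "tdd_mg_day"]


class CohortSchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class CohortValidationError(ValueError):
    """A cohort violates a structural invariant (e.g. duplicate ids)."""


@dataclass(frozen=True)
class VisitObservation:
    """One therapeutic-drug-monitoring visit.

    Parameters
    ----------
    time_months : float
        Time post-transplant in months; decimals allowed.
    c0 : float
        Tacrolimus trough concentration, ng/mL.
    tdd : float
        Total daily dose, mg/day.  Must be positive whenever ``c0`` is
        recorded so the dose-normalized trough C0/D is computable.
    creatinine : float or None
        Serum creatinine, umol/L; optional.
    """

    time_months: float
    c0: float
    tdd: float
    creatinine: float | None = None

    def check(self) -> None:
        """Raise :class:`CohortValidationError` on an invariant violation.

        Kept separate from construction so :func:`validate_cohort` can
        *report* bad values instead of being unable to represent them.
        """
        if self.time_months < 0:
            raise CohortValidationError(f"time_months must be >= 0, got {self.time_months}")
        if self.c0 < 0:
            raise CohortValidationError(f"c0 must be >= 0, got {self.c0}")
        if self.tdd <= 0:
            raise CohortValidationError(f"tdd must be > 0 when c0 is recorded, got {self.tdd}")

    @property
    def c0d(self) -> float:
        """Dose-normalized trough concentration, ng/mL per mg/day."""
        return self.c0 / self.tdd


@dataclass
class PatientRecord:
    """One transplant recipient with an ordered visit history."""

    patient_id: str
    sex: str
    age_years: float
    genotype: str
    acute_rejection: bool
    dgf: bool | None = None
    formulation: str | None = None
    visits: list[VisitObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.genotype not in GENOTYPES:
            raise CohortValidationError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.formulation is not None and self.formulation not in FORMULATIONS:
            raise CohortValidationError(
                f"formulation must be one of {FORMULATIONS}, got {self.formulation!r}"
            )
        self.visits = sorted(self.visits, key=lambda v: v.time_months)

    def visits_in_window(self, start: float, end: float) -> list[VisitObservation]:
        """Visits with ``start <= time_months <= end`` (both boundaries included)."""
        return [v for v in self.visits if start <= v.time_months <= end]


@dataclass
class Cohort:
    """A list of patients plus free-text provenance metadata."""

    patients: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortValidationError(f"duplicate patient_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass(frozen=True)
class ValidationIssue:
    level: str  # "error" | "warning"
    patient_id: str | None
    message: str


class ValidationReport(list):
    """List of :class:`ValidationIssue` with convenience predicates."""

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self if i.level == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self if i.level == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return bool(int(value))


def _opt_float(value) -> float | None:
    if value is None or value == "":
        return None
    f = float(value)
    return None if math.isnan(f) else f


def _check_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{table} table is missing required column(s): {', '.join(missing)}")


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort from ``<prefix>/patients.csv`` + ``<prefix>/visits.csv``.

    ``path`` may be a directory containing the two files, or the path of the
    patients table itself (the visits table is then looked up as a sibling
    named ``visits.csv`` or ``<stem with 'patients'->'visits'>.csv``).

    Raises
    ------
    CohortSchemaError
        Missing required column (named) or non-parsable numeric (with the
        offending row index).
    CohortValidationError
        Duplicate patient ids or invariant-violating values, reported with
        the offending row.
    """
    path = Path(path)
    if path.is_dir():
        patients_path = path / "patients.csv"
        visits_path = path / "visits.csv"
    else:
        patients_path = path
        candidate = path.with_name(path.name.replace("patients", "visits"))
        visits_path = candidate if candidate != path else path.with_name("visits.csv")
    if not patients_path.exists():
        raise FileNotFoundError(patients_path)
    if not visits_path.exists():
        raise FileNotFoundError(visits_path)

    pdf = pd.read_csv(patients_path, dtype={"patient_id": str}, float_precision="round_trip")
    vdf = pd.read_csv(visits_path, dtype={"patient_id": str}, float_precision="round_trip")
    _check_columns(pdf, _REQUIRED_PATIENT_COLUMNS, "patients")
    _check_columns(vdf, _REQUIRED_VISIT_COLUMNS, "visits")

    ids = pdf["patient_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise CohortValidationError(f"duplicate patient_id values in patients table: {dupes}")

    visits_by_patient: dict[str, list[VisitObservation]] = {pid: [] for pid in ids}
    for idx, row in vdf.iterrows():
        pid = row["patient_id"]
        if pid not in visits_by_patient:
            raise CohortValidationError(
                f"visits row {idx}: patient_id {pid!r} not present in patients table"
            )
        try:
            visit = VisitObservation(
                time_months=float(row["time_months"]),
                c0=float(row["c0_ng_ml"]),
                tdd=float(row["tdd_mg_day"]),
                creatinine=_opt_float(row.get("creatinine_umol_l")),
            )
            visit.check()
        except CohortValidationError as exc:
            raise CohortValidationError(f"visits row {idx} (patient {pid}): {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise CohortSchemaError(f"visits row {idx} (patient {pid}): non-parsable numeric: {exc}") from exc
        visits_by_patient[pid].append(visit)

    patients = []
    for idx, row in pdf.iterrows():
        try:
            sex = _SEX_FROM_CSV[str(row["sex"]).strip()]
        except KeyError as exc:
            raise CohortSchemaError(f"patients row {idx}: unrecognized sex {row['sex']!r}") from exc
        try:
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    sex=sex,
                    age_years=float(row["age_years"]),
                    genotype=str(row["cyp3a5"]).strip(),
                    acute_rejection=bool(int(row["acute_rejection"])),
                    dgf=_opt_bool(row.get("dgf")),
                    formulation=(None if pd.isna(row.get("formulation")) else str(row["formulation"]).strip()),
                    visits=visits_by_patient[row["patient_id"]],
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"patients row {idx}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise CohortSchemaError(f"patients row {idx}: non-parsable numeric: {exc}") from exc

    extra = [c for c in pdf.columns if c not in PATIENT_COLUMNS]
    provenance = {"source": str(patients_path)}
    if extra:
        provenance["extra_patient_columns"] = extra
    return Cohort(patients=patients, provenance=provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write ``patients.csv`` and ``visits.csv`` under directory ``path``.

    Numeric fields are emitted with ``repr`` round-trip precision so that
    ``read_cohort(write_cohort(c))`` reproduces ``c`` exactly.  Missing
    optional values become empty cells (never the string ``"nan"``).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prows = []
    vrows = []
    for p in cohort.patients:
        prows.append(
            {
                "patient_id": p.patient_id,
                "sex": _SEX_TO_CSV[p.sex],
                "age_years": repr(p.age_years),
                "cyp3a5": p.genotype,
                "acute_rejection": int(p.acute_rejection),
                "dgf": "" if p.dgf is None else int(p.dgf),
                "formulation": "" if p.formulation is None else p.formulation,
            }
        )
        for v in p.visits:
            vrows.append(
                {
                    "patient_id": p.patient_id,
                    "time_months": repr(v.time_months),
                    "c0_ng_ml": repr(v.c0),
                    "tdd_mg_day": repr(v.tdd),
                    "creatinine_umol_l": "" if v.creatinine is None else repr(v.creatinine),
                }
            )
    pd.DataFrame(prows, columns=PATIENT_COLUMNS).to_csv(path / "patients.csv", index=False)
    pd.DataFrame(vrows, columns=VISIT_COLUMNS).to_csv(path / "visits.csv", index=False)


def validate_cohort(
    cohort: Cohort,
    *,
    ipv_window: tuple[float, float] = (6.0, 12.0),
    min_ipv_samples: int = 4,
) -> ValidationReport:
    """Check cohort invariants; return a report instead of raising.

    Errors are genuine invariant violations (negative concentrations,
    unsorted visits).  A patient with fewer than ``min_ipv_samples`` trough
    samples inside the IPV window only triggers a *warning*: the intrapatient
    CV% is still computable from two samples but unreliable below roughly
    four, the lower end of the per-patient sample counts this pipeline is
    designed around.
    """
    report = ValidationReport()
    if not cohort.patients:
        report.append(ValidationIssue("error", None, "cohort is empty"))
        return report
    for p in cohort.patients:
        times = [v.time_months for v in p.visits]
        if times != sorted(times):
            report.append(ValidationIssue("error", p.patient_id, "visits not sorted by time_months"))
        for v in p.visits:
            if v.c0 < 0:
                report.append(ValidationIssue("error", p.patient_id, f"negative c0 {v.c0}"))
            if v.tdd <= 0:
                report.append(ValidationIssue("error", p.patient_id, f"non-positive tdd {v.tdd}"))
            if v.time_months < 0:
                report.append(ValidationIssue("error", p.patient_id, f"negative time {v.time_months}"))
        n_window = len(p.visits_in_window(*ipv_window))
        if n_window < min_ipv_samples:
            report.append(
                ValidationIssue(
                    "warning",
                    p.patient_id,
                    f"insufficient samples for IPV: {n_window} trough(s) in months "
                    f"{ipv_window[0]:g}-{ipv_window[1]:g} (fewer than {min_ipv_samples})",
                )
            )
    return report
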