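"""Clinical record model and cohort I/O for youth-onset GSD IV phenotyping.

A :class:`PatientRecord` holds one patient's coded clinical findings, onset
timing, vital status and transplant history as consolidated from all reports
of that patient.  Missingness is first-class: every categorical field has an
explicit ``unknown`` state and a finding that was never mentioned is
*unknown*, never *absent* — absence of involvement is an affirmative datum
recorded via the ``explicit_normal_*`` flags (set only when the original
authors stated normality).

Cohorts serialize losslessly to CSV (one row per patient, findings packed as
``code[:qualifier=value]`` tokens joined by ``;``) and to JSON (list of
record objects).  See ``docs/schema.md`` and ``src/gsd4/data/cohort.schema.json``.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "BodySystem",
    "ClinicalFinding",
    "FindingObservation",
    "NeuromuscularOnset",
    "VitalStatus",
    "TransplantStatus",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "CohortParseError",
    "validate_record",
    "read_cohort",
    "write_cohort",
]


class BodySystem(str, enum.Enum):
    """Organ system a qualifying finding is attributed to."""

    HEPATIC = "hepatic"
    NEUROMUSCULAR = "neuromuscular"
    CARDIAC = "cardiac"
    NON_QUALIFYING = "non_qualifying"


class ClinicalFinding(str, enum.Enum):
    """Coded clinical findings used for involvement assessment.

    Each code belongs to exactly one system group.  The two ``non_qualifying``
    codes are stored for provenance but never contribute to involvement or
    severity: neurological abnormalities not clearly attributable to GSD IV
    (e.g. childhood epilepsy, isolated language delay) and structural cardiac
    defects other than cardiomyopathy (e.g. VSD, double aortic arch).
    """

    # hepatic
    HEPATOMEGALY = "hepatomegaly"
    SPLENOMEGALY = "splenomegaly"
    VARICES = "varices"
    ASCITES = "ascites"
    ELEVATED_ALT = "elevated_alt"
    ELEVATED_GGT = "elevated_ggt"
    ELEVATED_ALP = "elevated_alp"
    PROLONGED_PT_INR = "prolonged_pt_inr"
    HYPERBILIRUBINEMIA = "hyperbilirubinemia"
    LOW_ALBUMIN = "low_albumin"
    FASTING_HYPOGLYCEMIA = "fasting_hypoglycemia"
    LIVER_FAILURE = "liver_failure"
    HEPATIC_SYNTHETIC_DYSFUNCTION = "hepatic_synthetic_dysfunction"
    JAUNDICE = "jaundice"
    GI_BLEED = "gi_bleed"
    # neuromuscular
    CONTRACTURES = "contractures"
    VENTILATOR_DEPENDENT_RESPIRATORY_WEAKNESS = "ventilator_dependent_respiratory_weakness"
    HYPOTONIA = "hypotonia"
    HYPOREFLEXIA = "hyporeflexia"
    ATROPHY_OR_HYPOTROPHY = "atrophy_or_hypotrophy"
    ABNORMAL_MOTOR_DEVELOPMENT = "abnormal_motor_development"
    ABNORMAL_EMG_OR_NCV = "abnormal_emg_or_ncv"
    WEAKNESS_OR_EXERCISE_INTOLERANCE = "weakness_or_exercise_intolerance"
    # cardiac
    CARDIOMYOPATHY = "cardiomyopathy"
    SYSTOLIC_DYSFUNCTION = "systolic_dysfunction"
    CARDIAC_HYPERTROPHY = "cardiac_hypertrophy"
    CARDIOMEGALY = "cardiomegaly"
    CONDUCTION_DEFECT = "conduction_defect"
    # non-qualifying (provenance only)
    OTHER_NEUROLOGICAL = "other_neurological"
    STRUCTURAL_CARDIAC_DEFECT = "structural_cardiac_defect"


_HEPATIC = {
    ClinicalFinding.HEPATOMEGALY,
    ClinicalFinding.SPLENOMEGALY,
    ClinicalFinding.VARICES,
    ClinicalFinding.ASCITES,
    ClinicalFinding.ELEVATED_ALT,
    ClinicalFinding.ELEVATED_GGT,
    ClinicalFinding.ELEVATED_ALP,
    ClinicalFinding.PROLONGED_PT_INR,
    ClinicalFinding.HYPERBILIRUBINEMIA,
    ClinicalFinding.LOW_ALBUMIN,
    ClinicalFinding.FASTING_HYPOGLYCEMIA,
    ClinicalFinding.LIVER_FAILURE,
    ClinicalFinding.HEPATIC_SYNTHETIC_DYSFUNCTION,
    ClinicalFinding.JAUNDICE,
    ClinicalFinding.GI_BLEED,
}
_NEUROMUSCULAR = {
    ClinicalFinding.CONTRACTURES,
    ClinicalFinding.VENTILATOR_DEPENDENT_RESPIRATORY_WEAKNESS,
    ClinicalFinding.HYPOTONIA,
    ClinicalFinding.HYPOREFLEXIA,
    ClinicalFinding.ATROPHY_OR_HYPOTROPHY,
    ClinicalFinding.ABNORMAL_MOTOR_DEVELOPMENT,
    ClinicalFinding.ABNORMAL_EMG_OR_NCV,
    ClinicalFinding.WEAKNESS_OR_EXERCISE_INTOLERANCE,
}
_CARDIAC = {
    ClinicalFinding.CARDIOMYOPATHY,
    ClinicalFinding.SYSTOLIC_DYSFUNCTION,
    ClinicalFinding.CARDIAC_HYPERTROPHY,
    ClinicalFinding.CARDIOMEGALY,
    ClinicalFinding.CONDUCTION_DEFECT,
}


def system_of(code: ClinicalFinding) -> BodySystem:
    """Return the system group a finding code belongs to (total mapping)."""
    if code in _HEPATIC:
        return BodySystem.HEPATIC
    if code in _NEUROMUSCULAR:
        return BodySystem.NEUROMUSCULAR
    if code in _CARDIAC:
        return BodySystem.CARDIAC
    return BodySystem.NON_QUALIFYING


class NeuromuscularOnset(str, enum.Enum):
    PRENATAL = "prenatal"
    AT_BIRTH = "at_birth"
    POSTNATAL = "postnatal"
    NONE_REPORTED = "none_reported"
    UNKNOWN = "unknown"


class VitalStatus(str, enum.Enum):
    ALIVE = "alive"
    DECEASED = "deceased"
    UNKNOWN = "unknown"


class TransplantStatus(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class FindingObservation(BaseModel):
    """One coded finding with its qualifiers.

    ``newborn_period_only`` marks hypoglycemia/hyperbilirubinemia limited to
    the immediate newborn period; ``heart_failure_context_only`` marks ascites
    occurring exclusively in the setting of heart failure.  Such findings are
    excluded from hepatic characterization.  ``platelet_count`` (per µl)
    qualifies splenomegaly for the portal-hypertension severe-feature rule.
    """

    model_config = ConfigDict(frozen=True)

    code: ClinicalFinding
    newborn_period_only: bool = False
    heart_failure_context_only: bool = False
    platelet_count: Optional[int] = None
    age_first_observed_months: Optional[float] = None


class PatientRecord(BaseModel):
    """Consolidated clinical state of one patient.

    Invariants are checked by :func:`validate_record` (which returns messages
    rather than raising, so inconsistent inputs can be reported in full).
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    findings: tuple[FindingObservation, ...] = ()
    neuromuscular_onset: NeuromuscularOnset = NeuromuscularOnset.UNKNOWN
    vital_status: VitalStatus = VitalStatus.UNKNOWN
    prenatal_death: bool = False
    age_at_death_months: Optional[float] = None
    age_at_last_followup_months: Optional[float] = None
    liver_transplant: TransplantStatus = TransplantStatus.UNKNOWN
    age_at_transplant_months: Optional[float] = None
    explicit_normal_hepatic: bool = False
    explicit_normal_neuromuscular: bool = False
    explicit_normal_cardiac: bool = False
    death_attributed_hepatic: Optional[bool] = None

    def findings_of(self, system: BodySystem) -> tuple[FindingObservation, ...]:
        return tuple(f for f in self.findings if system_of(f.code) is system)


class Cohort(BaseModel):
    """An ordered collection of patient records with unique ids."""

    model_config = ConfigDict(frozen=True)

    patients: tuple[PatientRecord, ...] = ()

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):  # iterate records, not pydantic fields
        return iter(self.patients)

    def ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


class CohortValidationError(ValueError):
    """Raised when a cohort or record violates the documented invariants."""


class CohortParseError(ValueError):
    """Raised when an input file does not conform to the cohort schema."""


_NEWBORN_QUALIFIABLE = {
    ClinicalFinding.FASTING_HYPOGLYCEMIA,
    ClinicalFinding.HYPERBILIRUBINEMIA,
}


def _is_excluded(obs: FindingObservation) -> bool:
    """True if the observation is removed from hepatic characterization."""
    if obs.newborn_period_only and obs.code in _NEWBORN_QUALIFIABLE:
        return True
    if obs.heart_failure_context_only and obs.code is ClinicalFinding.ASCITES:
        return True
    return False


def qualifying_findings(record: PatientRecord, system: BodySystem) -> list[FindingObservation]:
    """Findings that count toward involvement of *system* after exclusions."""
    out = []
    for obs in record.findings:
        if system_of(obs.code) is not system:
            continue
        if system is BodySystem.HEPATIC and _is_excluded(obs):
            continue
        out.append(obs)
    return out


def validate_record(record: PatientRecord) -> list[str]:
    """Check cross-field invariants; return human-readable violation messages.

    An empty list means the record is internally consistent.
    """
    v: list[str] = []
    pid = record.patient_id
    if not pid:
        v.append("patient_id must be non-empty")
    for obs in record.findings:
        if obs.newborn_period_only and obs.code not in _NEWBORN_QUALIFIABLE:
            v.append(
                f"{pid}: newborn_period_only is only meaningful for "
                f"fasting_hypoglycemia/hyperbilirubinemia, not {obs.code.value}"
            )
        if obs.heart_failure_context_only and obs.code is not ClinicalFinding.ASCITES:
            v.append(
                f"{pid}: heart_failure_context_only is only meaningful for ascites, "
                f"not {obs.code.value}"
            )
        if obs.platelet_count is not None and obs.platelet_count <= 0:
            v.append(f"{pid}: platelet_count must be > 0")
        if obs.age_first_observed_months is not None and obs.age_first_observed_months < 0:
            v.append(f"{pid}: age_first_observed_months must be >= 0")
    if record.prenatal_death:
        if record.vital_status is not VitalStatus.DECEASED:
            v.append(f"{pid}: prenatal_death requires vital_status=deceased")
        if record.age_at_death_months is not None:
            v.append(f"{pid}: prenatal_death excludes a postnatal age_at_death_months")
    if record.age_at_death_months is not None:
        if record.vital_status is not VitalStatus.DECEASED:
            v.append(f"{pid}: age_at_death_months requires vital_status=deceased")
        if record.age_at_death_months < 0:
            v.append(f"{pid}: age_at_death_months must be >= 0")
    if record.age_at_last_followup_months is not None and record.age_at_last_followup_months < 0:
        v.append(f"{pid}: age_at_last_followup_months must be >= 0")
    if record.liver_transplant is TransplantStatus.YES and record.age_at_transplant_months is None:
        v.append(f"{pid}: liver_transplant=yes requires age_at_transplant_months")
    if record.age_at_transplant_months is not None:
        if record.liver_transplant is not TransplantStatus.YES:
            v.append(f"{pid}: age_at_transplant_months requires liver_transplant=yes")
        elif record.age_at_transplant_months < 0:
            v.append(f"{pid}: age_at_transplant_months must be >= 0")
    for system, flag in (
        (BodySystem.HEPATIC, record.explicit_normal_hepatic),
        (BodySystem.NEUROMUSCULAR, record.explicit_normal_neuromuscular),
        (BodySystem.CARDIAC, record.explicit_normal_cardiac),
    ):
        if flag and qualifying_findings(record, system):
            v.append(
                f"{pid}: explicit_normal_{system.value} contradicts a qualifying "
                f"{system.value} finding"
            )
    return v


def validate_cohort(cohort: Cohort) -> list[str]:
    """Record-level violations plus patient_id uniqueness."""
    v: list[str] = []
    seen: set[str] = set()
    for rec in cohort.patients:
        if rec.patient_id in seen:
            v.append(f"duplicate patient_id: {rec.patient_id}")
        seen.add(rec.patient_id)
        v.extend(validate_record(rec))
    return v


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = [
    "patient_id",
    "findings",
    "neuromuscular_onset",
    "vital_status",
    "prenatal_death",
    "age_at_death_months",
    "age_at_last_followup_months",
    "liver_transplant",
    "age_at_transplant_months",
    "explicit_normal_hepatic",
    "explicit_normal_neuromuscular",
    "explicit_normal_cardiac",
    "death_attributed_hepatic",
]

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return repr(x)


def _finding_token(obs: FindingObservation) -> str:
    parts = [obs.code.value]
    if obs.newborn_period_only:
        parts.append("newborn_period_only=true")
    if obs.heart_failure_context_only:
        parts.append("heart_failure_context_only=true")
    if obs.platelet_count is not None:
        parts.append(f"platelet_count={obs.platelet_count}")
    if obs.age_first_observed_months is not None:
        parts.append(f"age_first_observed_months={_fmt_num(obs.age_first_observed_months)}")
    return ":".join(parts)


def _parse_finding_token(token: str, where: str) -> FindingObservation:
    parts = token.split(":")
    code_str, quals = parts[0].strip(), parts[1:]
    try:
        code = ClinicalFinding(code_str)
    except ValueError:
        raise CohortParseError(f"{where}: unknown finding code '{code_str}'") from None
    kwargs: dict = {"code": code}
    for q in quals:
        if "=" not in q:
            raise CohortParseError(f"{where}: malformed qualifier '{q}' in finding '{token}'")
        key, _, val = q.partition("=")
        key = key.strip()
        val = val.strip()
        if key in ("newborn_period_only", "heart_failure_context_only"):
            if val.lower() not in _BOOL_TOKENS:
                raise CohortParseError(f"{where}: non-boolean qualifier value '{val}'")
            kwargs[key] = _BOOL_TOKENS[val.lower()]
        elif key == "platelet_count":
            try:
                kwargs[key] = int(val)
            except ValueError:
                raise CohortParseError(f"{where}: platelet_count must be an integer") from None
        elif key == "age_first_observed_months":
            try:
                kwargs[key] = float(val)
            except ValueError:
                raise CohortParseError(
                    f"{where}: age_first_observed_months must be numeric"
                ) from None
        else:
            raise CohortParseError(f"{where}: unknown finding qualifier '{key}'")
    return FindingObservation(**kwargs)


def record_to_dict(record: PatientRecord) -> dict:
    """JSON-ready dict; optional fields that are unset are omitted."""
    d: dict = {
        "patient_id": record.patient_id,
        "findings": [],
        "neuromuscular_onset": record.neuromuscular_onset.value,
        "vital_status": record.vital_status.value,
        "prenatal_death": record.prenatal_death,
        "liver_transplant": record.liver_transplant.value,
        "explicit_normal_hepatic": record.explicit_normal_hepatic,
        "explicit_normal_neuromuscular": record.explicit_normal_neuromuscular,
        "explicit_normal_cardiac": record.explicit_normal_cardiac,
    }
    for obs in record.findings:
        o: dict = {"code": obs.code.value}
        if obs.newborn_period_only:
            o["newborn_period_only"] = True
        if obs.heart_failure_context_only:
            o["heart_failure_context_only"] = True
        if obs.platelet_count is not None:
            o["platelet_count"] = obs.platelet_count
        if obs.age_first_observed_months is not None:
            o["age_first_observed_months"] = obs.age_first_observed_months
        d["findings"].append(o)
    if record.age_at_death_months is not None:
        d["age_at_death_months"] = record.age_at_death_months
    if record.age_at_last_followup_months is not None:
        d["age_at_last_followup_months"] = record.age_at_last_followup_months
    if record.age_at_transplant_months is not None:
        d["age_at_transplant_months"] = record.age_at_transplant_months
    if record.death_attributed_hepatic is not None:
        d["death_attributed_hepatic"] = record.death_attributed_hepatic
    return d


def _enum_from(value: str, enum_cls, field: str, where: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise CohortParseError(
            f"{where}: field '{field}' has invalid value '{value}' (allowed: {allowed})"
        ) from None


def record_from_dict(d: dict, where: str = "record") -> PatientRecord:
    """Build a record from a JSON object; missing fields become unknown."""
    if not isinstance(d, dict):
        raise CohortParseError(f"{where}: expected an object, got {type(d).__name__}")
    unknown = set(d) - set(_CSV_COLUMNS)
    if unknown:
        raise CohortParseError(f"{where}: unknown field(s) {sorted(unknown)}")
    if "patient_id" not in d or not str(d["patient_id"]).strip():
        raise CohortParseError(f"{where}: missing patient_id")
    findings = []
    for i, o in enumerate(d.get("findings") or []):
        if isinstance(o, str):
            findings.append(_parse_finding_token(o, f"{where} finding {i}"))
            continue
        if not isinstance(o, dict) or "code" not in o:
            raise CohortParseError(f"{where}: finding {i} must be an object with a 'code'")
        code = _enum_from(o["code"], ClinicalFinding, "code", f"{where} finding {i}")
        findings.append(
            FindingObservation(
                code=code,
                newborn_period_only=bool(o.get("newborn_period_only", False)),
                heart_failure_context_only=bool(o.get("heart_failure_context_only", False)),
                platelet_count=o.get("platelet_count"),
                age_first_observed_months=o.get("age_first_observed_months"),
            )
        )

    def _num(field: str) -> Optional[float]:
        val = d.get(field)
        if val is None or val == "":
            return None
        try:
            out = float(val)
        except (TypeError, ValueError):
            raise CohortParseError(f"{where}: field '{field}' must be numeric") from None
        if math.isnan(out):
            return None
        return out

    def _bool(field: str, default: bool = False) -> bool:
        val = d.get(field)
        if val is None or val == "":
            return default
        if isinstance(val, bool):
            return val
        if str(val).lower() in _BOOL_TOKENS:
            return _BOOL_TOKENS[str(val).lower()]
        raise CohortParseError(f"{where}: field '{field}' must be boolean")

    dah = d.get("death_attributed_hepatic")
    if dah is not None and dah != "":
        if isinstance(dah, bool):
            pass
        elif str(dah).lower() in _BOOL_TOKENS:
            dah = _BOOL_TOKENS[str(dah).lower()]
        else:
            raise CohortParseError(f"{where}: death_attributed_hepatic must be boolean")
    else:
        dah = None

    return PatientRecord(
        patient_id=str(d["patient_id"]),
        findings=tuple(findings),
        neuromuscular_onset=_enum_from(
            d.get("neuromuscular_onset") or "unknown", NeuromuscularOnset,
            "neuromuscular_onset", where),
        vital_status=_enum_from(
            d.get("vital_status") or "unknown", VitalStatus, "vital_status", where),
        prenatal_death=_bool("prenatal_death"),
        age_at_death_months=_num("age_at_death_months"),
        age_at_last_followup_months=_num("age_at_last_followup_months"),
        liver_transplant=_enum_from(
            d.get("liver_transplant") or "unknown", TransplantStatus, "liver_transplant", where),
        age_at_transplant_months=_num("age_at_transplant_months"),
        explicit_normal_hepatic=_bool("explicit_normal_hepatic"),
        explicit_normal_neuromuscular=_bool("explicit_normal_neuromuscular"),
        explicit_normal_cardiac=_bool("explicit_normal_cardiac"),
        death_attributed_hepatic=dah,
    )


def _record_to_csv_row(record: PatientRecord) -> dict:
    return {
        "patient_id": record.patient_id,
        "findings": ";".join(_finding_token(o) for o in record.findings),
        "neuromuscular_onset": record.neuromuscular_onset.value,
        "vital_status": record.vital_status.value,
        "prenatal_death": "true" if record.prenatal_death else "false",
        "age_at_death_months": _fmt_num(record.age_at_death_months),
        "age_at_last_followup_months": _fmt_num(record.age_at_last_followup_months),
        "liver_transplant": record.liver_transplant.value,
        "age_at_transplant_months": _fmt_num(record.age_at_transplant_months),
        "explicit_normal_hepatic": "true" if record.explicit_normal_hepatic else "false",
        "explicit_normal_neuromuscular": "true" if record.explicit_normal_neuromuscular else "false",
        "explicit_normal_cardiac": "true" if record.explicit_normal_cardiac else "false",
        "death_attributed_hepatic": (
            "" if record.death_attributed_hepatic is None
            else ("true" if record.death_attributed_hepatic else "false")
        ),
    }


def _record_from_csv_row(row: dict, where: str) -> PatientRecord:
    d = dict(row)
    tokens = (d.pop("findings", "") or "").strip()
    d["findings"] = [t for t in (s.strip() for s in tokens.split(";")) if t] if tokens else []
    return record_from_dict(d, where)


def read_cohort(path: str | Path, format: Optional[str] = None) -> Cohort:
    """Read and validate a cohort from a CSV or JSON file.

    ``format`` defaults to the file extension.  Unknown or empty fields map
    to the corresponding ``unknown`` states — never to a negative finding.

    Raises :class:`CohortParseError` (naming the offending row and field) on
    schema violations and :class:`CohortValidationError` on invariant
    violations such as duplicate patient ids.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported cohort format: {fmt!r}")
    if fmt == "csv":
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise CohortParseError(f"{path}: empty file (expected a header row)") from None
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise CohortParseError(f"{path}: missing column(s) {sorted(missing)}")
        extra = set(df.columns) - set(_CSV_COLUMNS)
        if extra:
            raise CohortParseError(f"{path}: unknown column(s) {sorted(extra)}")
        records = [
            _record_from_csv_row(row, f"{path} row {i + 2}")
            for i, row in enumerate(df.to_dict(orient="records"))
        ]
    else:
        with open(path, encoding="utf-8") as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"{path}: invalid JSON ({exc})") from None
        if isinstance(payload, dict) and "patients" in payload:
            payload = payload["patients"]
        if not isinstance(payload, list):
            raise CohortParseError(f"{path}: expected a list of patient records")
        records = [record_from_dict(d, f"{path} record {i}") for i, d in enumerate(payload)]
    cohort = Cohort(patients=tuple(records))
    violations = validate_cohort(cohort)
    if violations:
        raise CohortValidationError(
            f"{path}: {len(violations)} invariant violation(s):\n  " + "\n  ".join(violations)
        )
    return cohort


def write_cohort(cohort: Cohort, path: str | Path, format: Optional[str] = None) -> None:
    """Write a cohort to CSV or JSON such that :func:`read_cohort` round-trips."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported cohort format: {fmt!r}")
    if fmt == "csv":
        df = pd.DataFrame(
            [_record_to_csv_row(r) for r in cohort.patients], columns=_CSV_COLUMNS
        )
        df.to_csv(path, index=False)
    else:
        payload = [record_to_dict(r) for r in cohort.patients]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


def cohort_from_records(records: Iterable[PatientRecord]) -> Cohort:
    """Build a cohort, raising :class:`CohortValidationError` on violations."""
    cohort = Cohort(patients=tuple(records))
    violations = validate_cohort(cohort)
    if violations:
        raise CohortValidationError(
            f"{len(violations)} invariant violation(s):\n  " + "\n  ".join(violations)
        )
    return cohort
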