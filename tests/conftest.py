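from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from gsd4 import (
    ClinicalFinding,
    FindingObservation,
    NeuromuscularOnset,
    PatientRecord,
    TransplantStatus,
    VitalStatus,
    reference_cohort,
)
from gsd4.records import BodySystem, qualifying_findings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def ref_cohort():
    """Canonical deterministic reference cohort (146 patients)."""
    return reference_cohort()


@pytest.fixture(scope="session")
def ref_csv_path():
    return DATA_DIR / "reference_cohort.csv"


@pytest.fixture(scope="session")
def ref_json_path():
    return DATA_DIR / "reference_cohort.json"


# --- hypothesis strategies --------------------------------------------------

_tenths = st.integers(0, 3000).map(lambda t: t / 10.0)


@st.composite
def finding_observations(draw) -> FindingObservation:
    code = draw(st.sampled_from(list(ClinicalFinding)))
    kwargs = {"code": code}
    if code in (ClinicalFinding.FASTING_HYPOGLYCEMIA, ClinicalFinding.HYPERBILIRUBINEMIA):
        kwargs["newborn_period_only"] = draw(st.booleans())
    if code is ClinicalFinding.ASCITES:
        kwargs["heart_failure_context_only"] = draw(st.booleans())
    if code is ClinicalFinding.SPLENOMEGALY:
        kwargs["platelet_count"] = draw(
            st.one_of(st.none(), st.integers(50_000, 400_000))
        )
    if draw(st.booleans()):
        kwargs["age_first_observed_months"] = draw(_tenths)
    return FindingObservation(**kwargs)


@st.composite
def patient_records(draw, patient_id: str = "P1") -> PatientRecord:
    """Arbitrary *valid* postnatal patient records."""
    findings = tuple(draw(st.lists(finding_observations(), max_size=6)))
    vital = draw(st.sampled_from(list(VitalStatus)))
    death_age = None
    if vital is VitalStatus.DECEASED and draw(st.booleans()):
        death_age = draw(_tenths)
    transplant = draw(st.sampled_from(list(TransplantStatus)))
    transplant_age = draw(_tenths) if transplant is TransplantStatus.YES else None
    followup = draw(st.one_of(st.none(), _tenths))
    rec = PatientRecord(
        patient_id=patient_id,
        findings=findings,
        neuromuscular_onset=draw(st.sampled_from(list(NeuromuscularOnset))),
        vital_status=vital,
        prenatal_death=False,
        age_at_death_months=death_age,
        age_at_last_followup_months=followup,
        liver_transplant=transplant,
        age_at_transplant_months=transplant_age,
        explicit_normal_hepatic=draw(st.booleans()),
        explicit_normal_neuromuscular=draw(st.booleans()),
        explicit_normal_cardiac=draw(st.booleans()),
        death_attributed_hepatic=draw(st.one_of(st.none(), st.booleans())),
    )
    # drop explicit-normal flags contradicted by a qualifying finding
    upd = {}
    for system, field in (
        (BodySystem.HEPATIC, "explicit_normal_hepatic"),
        (BodySystem.NEUROMUSCULAR, "explicit_normal_neuromuscular"),
        (BodySystem.CARDIAC, "explicit_normal_cardiac"),
    ):
        if getattr(rec, field) and qualifying_findings(rec, system):
            upd[field] = False
    return rec.model_copy(update=upd) if upd else rec
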