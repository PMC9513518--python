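"""Two-part N/H phenotype scoring, severe-feature rule, and subtyping."""

import itertools

import pytest
from hypothesis import given, settings

from gsd4 import (
    ClinicalFinding,
    FindingObservation,
    HScore,
    InvolvementStatus,
    NeuromuscularOnset,
    NScore,
    PatientRecord,
    PhenotypeScore,
    PrenatalDeathError,
    SubtypeCategory,
    TransplantStatus,
    VitalStatus,
    assess_hepatic,
    assess_neuromuscular,
    assign_phenotype_score,
    classify_subtype,
    has_severe_hepatic_features,
    score_hepatic,
    score_neuromuscular,
)
from gsd4.records import BodySystem, system_of

from conftest import patient_records

P = InvolvementStatus.PRESENT
A = InvolvementStatus.ABSENT
U = InvolvementStatus.UNKNOWN


def rec(findings=(), **kwargs):
    kwargs.setdefault("patient_id", "L1")
    return PatientRecord(findings=tuple(findings), **kwargs)


def obs(code, **kw):
    return FindingObservation(code=code, **kw)


class TestSevereFeatures:
    def test_splenomegaly_with_thrombocytopenia(self):
        r = rec([obs(ClinicalFinding.SPLENOMEGALY, platelet_count=120_000)])
        assert has_severe_hepatic_features(r) is True

    def test_splenomegaly_at_threshold_is_not_severe(self):
        # strict < 150,000/ul boundary
        r = rec([obs(ClinicalFinding.SPLENOMEGALY, platelet_count=150_000)])
        assert has_severe_hepatic_features(r) is False
        r2 = rec([obs(ClinicalFinding.SPLENOMEGALY, platelet_count=149_999)])
        assert has_severe_hepatic_features(r2) is True

    def test_splenomegaly_with_normal_platelets_not_severe(self):
        r = rec([obs(ClinicalFinding.SPLENOMEGALY, platelet_count=200_000)])
        assert has_severe_hepatic_features(r) is False

    def test_mild_findings_are_not_severe(self):
        r = rec([obs(ClinicalFinding.HEPATOMEGALY), obs(ClinicalFinding.ELEVATED_ALT)])
        assert has_severe_hepatic_features(r) is False

    @pytest.mark.parametrize(
        "code",
        [
            ClinicalFinding.LIVER_FAILURE,
            ClinicalFinding.HEPATIC_SYNTHETIC_DYSFUNCTION,
            ClinicalFinding.JAUNDICE,
            ClinicalFinding.HYPERBILIRUBINEMIA,
            ClinicalFinding.ASCITES,
            ClinicalFinding.VARICES,
            ClinicalFinding.GI_BLEED,
        ],
    )
    def test_severe_feature_list(self, code):
        assert has_severe_hepatic_features(rec([obs(code)])) is True

    def test_newborn_period_hyperbilirubinemia_not_severe(self):
        r = rec([obs(ClinicalFinding.HYPERBILIRUBINEMIA, newborn_period_only=True)])
        assert has_severe_hepatic_features(r) is False

    def test_heart_failure_ascites_not_severe(self):
        r = rec([obs(ClinicalFinding.ASCITES, heart_failure_context_only=True)])
        assert has_severe_hepatic_features(r) is False


class TestNeuromuscularScore:
    def test_onset_at_birth_early_death_is_n3(self):
        r = rec(
            [obs(ClinicalFinding.HYPOTONIA)],
            neuromuscular_onset=NeuromuscularOnset.AT_BIRTH,
            vital_status=VitalStatus.DECEASED,
            age_at_death_months=2.0,
        )
        assert score_neuromuscular(r, P) is NScore.N3

    def test_onset_at_birth_long_survival_is_n2(self):
        r = rec(
            [obs(ClinicalFinding.CONTRACTURES)],
            neuromuscular_onset=NeuromuscularOnset.AT_BIRTH,
            vital_status=VitalStatus.ALIVE,
            age_at_last_followup_months=120.0,
        )
        assert score_neuromuscular(r, P) is NScore.N2

    def test_postnatal_onset_is_n1(self):
        r = rec(
            [obs(ClinicalFinding.WEAKNESS_OR_EXERCISE_INTOLERANCE)],
            neuromuscular_onset=NeuromuscularOnset.POSTNATAL,
            vital_status=VitalStatus.ALIVE,
        )
        assert score_neuromuscular(r, P) is NScore.N1

    def test_absent_involvement_is_n0(self):
        assert score_neuromuscular(rec(explicit_normal_neuromuscular=True), A) is NScore.N0

    def test_censored_before_six_months_is_unscorable(self):
        r = rec(
            [obs(ClinicalFinding.HYPOTONIA)],
            neuromuscular_onset=NeuromuscularOnset.AT_BIRTH,
            vital_status=VitalStatus.ALIVE,
            age_at_last_followup_months=4.0,
        )
        assert score_neuromuscular(r, P) is NScore.UNSCORABLE

    def test_death_at_exactly_six_months_counts_as_survival(self):
        r = rec(
            [obs(ClinicalFinding.HYPOTONIA)],
            neuromuscular_onset=NeuromuscularOnset.PRENATAL,
            vital_status=VitalStatus.DECEASED,
            age_at_death_months=6.0,
        )
        assert score_neuromuscular(r, P) is NScore.N2

    def test_unknown_onset_is_unscorable(self):
        r = rec([obs(ClinicalFinding.HYPOTONIA)])
        assert score_neuromuscular(r, P) is NScore.UNSCORABLE

    def test_unknown_involvement_is_unscorable(self):
        assert score_neuromuscular(rec(), U) is NScore.UNSCORABLE


class TestHepaticScore:
    def test_liver_failure_with_early_transplant_is_h3(self):
        r = rec(
            [obs(ClinicalFinding.LIVER_FAILURE)],
            liver_transplant=TransplantStatus.YES,
            age_at_transplant_months=18.0,
            vital_status=VitalStatus.ALIVE,
            age_at_last_followup_months=96.0,
        )
        assert score_hepatic(r, P) is HScore.H3

    def test_severe_features_with_late_death_is_h2(self):
        # survived past 5 years without transplant, later died (e.g. HCC at 13 y)
        r = rec(
            [obs(ClinicalFinding.VARICES)],
            liver_transplant=TransplantStatus.NO,
            vital_status=VitalStatus.DECEASED,
            age_at_death_months=156.0,
        )
        assert score_hepatic(r, P) is HScore.H2

    def test_mild_involvement_is_h1_regardless_of_outcome(self):
        r = rec(
            [obs(ClinicalFinding.HEPATOMEGALY), obs(ClinicalFinding.ELEVATED_ALT)],
            vital_status=VitalStatus.ALIVE,
            age_at_last_followup_months=96.0,
        )
        assert score_hepatic(r, P) is HScore.H1

    def test_absent_involvement_is_h0(self):
        assert score_hepatic(rec(explicit_normal_hepatic=True), A) is HScore.H0

    def test_death_before_five_years_is_h3(self):
        r = rec(
            [obs(ClinicalFinding.ASCITES)],
            vital_status=VitalStatus.DECEASED,
            age_at_death_months=20.0,
        )
        assert score_hepatic(r, P) is HScore.H3

    def test_severe_censored_young_is_unscorable(self):
        r = rec(
            [obs(ClinicalFinding.VARICES)],
            liver_transplant=TransplantStatus.NO,
            vital_status=VitalStatus.ALIVE,
            age_at_last_followup_months=30.0,
        )
        assert score_hepatic(r, P) is HScore.UNSCORABLE

    def test_late_transplant_still_h2(self):
        r = rec(
            [obs(ClinicalFinding.VARICES)],
            liver_transplant=TransplantStatus.YES,
            age_at_transplant_months=80.0,
            vital_status=VitalStatus.ALIVE,
            age_at_last_followup_months=120.0,
        )
        assert score_hepatic(r, P) is HScore.H2

    def test_unknown_transplant_history_blocks_h2(self):
        # survived past 5 years but transplant history indeterminate
        r = rec(
            [obs(ClinicalFinding.VARICES)],
            vital_status=VitalStatus.ALIVE,
            age_at_last_followup_months=120.0,
        )
        assert score_hepatic(r, P) is HScore.UNSCORABLE

    def test_death_attribution_switch(self):
        r = rec(
            [obs(ClinicalFinding.VARICES)],
            vital_status=VitalStatus.DECEASED,
            age_at_death_months=20.0,
            death_attributed_hepatic=False,
            liver_transplant=TransplantStatus.NO,
        )
        assert score_hepatic(r, P) is HScore.H3
        assert (
            score_hepatic(r, P, require_hepatic_death_attribution=True)
            is HScore.UNSCORABLE
        )
        r2 = r.model_copy(update={"death_attributed_hepatic": True})
        assert score_hepatic(r2, P, require_hepatic_death_attribution=True) is HScore.H3


class TestAssignScore:
    def test_neuromuscular_only_neonate(self):
        r = rec(
            [obs(ClinicalFinding.HYPOTONIA)],
            neuromuscular_onset=NeuromuscularOnset.AT_BIRTH,
            vital_status=VitalStatus.DECEASED,
            age_at_death_months=1.0,
            explicit_normal_hepatic=True,
        )
        s = assign_phenotype_score(r)
        assert (s.n, s.h) == (NScore.N3, HScore.H0)
        assert str(s) == "N3-H0"

    def test_mixed_congenital_neuromuscular_with_classic_hepatic(self):
        # hypotonia from birth + hepatomegaly + jaundice, died at 20 months
        r = rec(
            [
                obs(ClinicalFinding.HYPOTONIA),
                obs(ClinicalFinding.HEPATOMEGALY),
                obs(ClinicalFinding.JAUNDICE),
            ],
            neuromuscular_onset=NeuromuscularOnset.AT_BIRTH,
            vital_status=VitalStatus.DECEASED,
            age_at_death_months=20.0,
        )
        s = assign_phenotype_score(r)
        assert (s.n, s.h) == (NScore.N2, HScore.H3)
        assert classify_subtype(s) is SubtypeCategory.MIXED

    def test_exclusively_cardiac_patient_is_n0_h0(self):
        r = rec(
            [obs(ClinicalFinding.CARDIOMYOPATHY)],
            explicit_normal_hepatic=True,
            explicit_normal_neuromuscular=True,
        )
        s = assign_phenotype_score(r)
        assert (s.n, s.h) == (NScore.N0, HScore.H0)
        assert classify_subtype(s) is SubtypeCategory.NO_HEPATIC_NO_NEUROMUSCULAR

    def test_prenatal_death_is_usage_error(self):
        r = rec(prenatal_death=True, vital_status=VitalStatus.DECEASED)
        with pytest.raises(PrenatalDeathError):
            assign_phenotype_score(r)


class TestClassifySubtype:
    @pytest.mark.parametrize(
        "n, h, expected",
        [
            (NScore.N3, HScore.H0, SubtypeCategory.PERINATAL_CONGENITAL_NEUROMUSCULAR),
            (NScore.N1, HScore.H0, SubtypeCategory.JUVENILE_NEUROMUSCULAR),
            (NScore.N0, HScore.H3, SubtypeCategory.CLASSIC_HEPATIC),
            (NScore.N0, HScore.H1, SubtypeCategory.NON_PROGRESSIVE_HEPATIC),
            (NScore.N1, HScore.H1, SubtypeCategory.MIXED),
            (NScore.UNSCORABLE, HScore.H1, SubtypeCategory.UNCLASSIFIABLE),
        ],
    )
    def test_examples(self, n, h, expected):
        assert classify_subtype(PhenotypeScore(n=n, h=h)) is expected

    def test_total_mapping_against_decision_table(self):
        """All 25 (N, H) combinations agree with an independent table."""

        def oracle(n: NScore, h: HScore) -> SubtypeCategory:
            if n is NScore.UNSCORABLE or h is HScore.UNSCORABLE:
                return SubtypeCategory.UNCLASSIFIABLE
            table = {
                ("N0", "H0"): SubtypeCategory.NO_HEPATIC_NO_NEUROMUSCULAR,
                ("N0", "H1"): SubtypeCategory.NON_PROGRESSIVE_HEPATIC,
                ("N0", "H2"): SubtypeCategory.INTERMEDIATE_HEPATIC,
                ("N0", "H3"): SubtypeCategory.CLASSIC_HEPATIC,
                ("N1", "H0"): SubtypeCategory.JUVENILE_NEUROMUSCULAR,
                ("N2", "H0"): SubtypeCategory.INTERMEDIATE_NEUROMUSCULAR,
                ("N3", "H0"): SubtypeCategory.PERINATAL_CONGENITAL_NEUROMUSCULAR,
            }
            return table.get((n.value, h.value), SubtypeCategory.MIXED)

        combos = list(itertools.product(NScore, HScore))
        assert len(combos) == 25
        for n, h in combos:
            assert classify_subtype(PhenotypeScore(n=n, h=h)) is oracle(n, h), (n, h)

    def test_established_subtypes_are_exactly_four_cells(self):
        established = set()
        for n, h in itertools.product(NScore, HScore):
            cat = classify_subtype(PhenotypeScore(n=n, h=h))
            if cat in (
                SubtypeCategory.PERINATAL_CONGENITAL_NEUROMUSCULAR,
                SubtypeCategory.JUVENILE_NEUROMUSCULAR,
                SubtypeCategory.CLASSIC_HEPATIC,
                SubtypeCategory.NON_PROGRESSIVE_HEPATIC,
            ):
                established.add((n, h))
        assert established == {
            (NScore.N3, HScore.H0),
            (NScore.N1, HScore.H0),
            (NScore.N0, HScore.H3),
            (NScore.N0, HScore.H1),
        }


# --- independent exhaustive decision-table oracle ---------------------------

_SEVERE = {
    "liver_failure", "hepatic_synthetic_dysfunction", "jaundice",
    "hyperbilirubinemia", "ascites", "varices", "gi_bleed",
}


def _oracle_score(r: PatientRecord) -> tuple[NScore, HScore]:
    """Flat re-derivation of the full decision tree, written independently."""
    hep, nm = [], []
    for f in r.findings:
        s = system_of(f.code)
        if s is BodySystem.HEPATIC:
            if f.newborn_period_only or f.heart_failure_context_only:
                continue
            hep.append(f)
        elif s is BodySystem.NEUROMUSCULAR:
            nm.append(f)
    ages = [
        x for x in (
            r.age_at_death_months, r.age_at_last_followup_months,
            r.age_at_transplant_months,
        ) if x is not None
    ]
    max_age = max(ages, default=None)
    died_before = (
        lambda cutoff: r.vital_status is VitalStatus.DECEASED
        and r.age_at_death_months is not None
        and r.age_at_death_months < cutoff
    )

    # N component
    if nm:
        if r.neuromuscular_onset is NeuromuscularOnset.POSTNATAL:
            n = NScore.N1
        elif r.neuromuscular_onset in (
            NeuromuscularOnset.PRENATAL, NeuromuscularOnset.AT_BIRTH
        ):
            if died_before(6):
                n = NScore.N3
            elif max_age is not None and max_age >= 6:
                n = NScore.N2
            else:
                n = NScore.UNSCORABLE
        else:
            n = NScore.UNSCORABLE
    elif r.explicit_normal_neuromuscular:
        n = NScore.N0
    else:
        n = NScore.UNSCORABLE

    # H component
    if hep:
        severe = any(
            f.code.value in _SEVERE
            or (
                f.code.value == "splenomegaly"
                and f.platelet_count is not None
                and f.platelet_count < 150_000
            )
            for f in hep
        )
        if not severe:
            h = HScore.H1
        else:
            lt_before = (
                r.liver_transplant is TransplantStatus.YES
                and r.age_at_transplant_months is not None
                and r.age_at_transplant_months < 60
            )
            no_lt_before = r.liver_transplant is TransplantStatus.NO or (
                r.liver_transplant is TransplantStatus.YES
                and r.age_at_transplant_months is not None
                and r.age_at_transplant_months >= 60
            )
            if lt_before or died_before(60):
                h = HScore.H3
            elif max_age is not None and max_age >= 60 and no_lt_before:
                h = HScore.H2
            else:
                h = HScore.UNSCORABLE
    elif r.explicit_normal_hepatic:
        h = HScore.H0
    else:
        h = HScore.UNSCORABLE
    return n, h


@settings(max_examples=2000, deadline=None)
@given(patient_records())
def test_pipeline_agrees_with_independent_decision_table(record):
    """Randomized records score identically under the independent oracle."""
    s = assign_phenotype_score(record)
    assert (s.n, s.h) == _oracle_score(record)


@given(patient_records())
def test_adding_severe_feature_never_lowers_h(record):
    s_before = assign_phenotype_score(record)
    worse = record.model_copy(
        update={
            "findings": record.findings + (obs(ClinicalFinding.LIVER_FAILURE),),
            "explicit_normal_hepatic": False,
        }
    )
    s_after = assign_phenotype_score(worse)
    if s_before.h.rank is not None and s_after.h.rank is not None:
        assert s_after.h.rank >= s_before.h.rank


@given(patient_records())
def test_shortening_survival_never_softens_scores(record):
    """Moving a death below a cutoff never yields a milder severity class."""
    if record.vital_status is not VitalStatus.DECEASED or record.age_at_death_months is None:
        return
    earlier = record.model_copy(update={"age_at_death_months": 1.0})
    s_before = assign_phenotype_score(record)
    s_after = assign_phenotype_score(earlier)
    if s_before.n.rank is not None and s_after.n.rank is not None:
        assert s_after.n.rank >= s_before.n.rank
    if s_before.h.rank is not None and s_after.h.rank is not None:
        assert s_after.h.rank >= s_before.h.rank
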