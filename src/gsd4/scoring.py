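"""Four-point hepatic and neuromuscular phenotype scoring and subtyping.

The two-part score operationalizes the established youth-onset GSD IV
subtype definitions into ordinal scales:

Neuromuscular (onset timing x survival):
  N0  no neuromuscular involvement
  N1  onset of neuromuscular manifestations after birth (juvenile)
  N2  onset at or before birth, survival to >=6 months (intermediate)
  N3  onset at or before birth, death at <6 months (perinatal-congenital)

Hepatic (severity x transplant-free survival):
  H0  no hepatic involvement
  H1  hepatic involvement without severe features (non-progressive)
  H2  severe features, surviving to >=5 years without LT (intermediate)
  H3  severe features leading to LT or death at <5 years (classic)

"Severe hepatic features" = any history of liver failure or synthetic
dysfunction; jaundice or hyperbilirubinemia; ascites; varices or GI bleed;
or splenomegaly with thrombocytopenia (<150,000/ul, consistent with definite
clinically evident portal hypertension).  The newborn-period and
heart-failure exclusions apply here exactly as in involvement assessment.

Boundary semantics: the "<6 months" / "<5 years" cutoffs are strict; death
at exactly the cutoff counts as survival to it.  Five years is 60 months.
Patients censored alive before a cutoff that their score depends on are
*unscorable* for that component, never optimistically assigned the milder
score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .involvement import (
    InvolvementProfile,
    InvolvementStatus,
    PrenatalDeathError,
    assess_profile,
)
from .records import (
    BodySystem,
    ClinicalFinding,
    PatientRecord,
    TransplantStatus,
    VitalStatus,
    qualifying_findings,
)

__all__ = [
    "NScore",
    "HScore",
    "PhenotypeScore",
    "SubtypeCategory",
    "THROMBOCYTOPENIA_THRESHOLD",
    "NEONATAL_CUTOFF_MONTHS",
    "HEPATIC_CUTOFF_MONTHS",
    "has_severe_hepatic_features",
    "score_neuromuscular",
    "score_hepatic",
    "assign_phenotype_score",
    "classify_subtype",
]

THROMBOCYTOPENIA_THRESHOLD = 150_000  # platelets per ul
NEONATAL_CUTOFF_MONTHS = 6.0
HEPATIC_CUTOFF_MONTHS = 60.0


class NScore(str, enum.Enum):
    N0 = "N0"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    UNSCORABLE = "N?"

    @property
    def rank(self) -> Optional[int]:
        """Numeric severity (0-3), or None if unscorable."""
        return None if self is NScore.UNSCORABLE else int(self.value[1])


class HScore(str, enum.Enum):
    H0 = "H0"
    H1 = "H1"
    H2 = "H2"
    H3 = "H3"
    UNSCORABLE = "H?"

    @property
    def rank(self) -> Optional[int]:
        return None if self is HScore.UNSCORABLE else int(self.value[1])


class SubtypeCategory(str, enum.Enum):
    """Position of a scored patient relative to the four established subtypes."""

    PERINATAL_CONGENITAL_NEUROMUSCULAR = "perinatal_congenital_neuromuscular"  # N3-H0
    JUVENILE_NEUROMUSCULAR = "juvenile_neuromuscular"                          # N1-H0
    CLASSIC_HEPATIC = "classic_hepatic"                                        # N0-H3
    NON_PROGRESSIVE_HEPATIC = "non_progressive_hepatic"                        # N0-H1
    INTERMEDIATE_NEUROMUSCULAR = "intermediate_neuromuscular"                  # N2-H0
    INTERMEDIATE_HEPATIC = "intermediate_hepatic"                              # N0-H2
    MIXED = "mixed"                                                            # N>0 and H>0
    NO_HEPATIC_NO_NEUROMUSCULAR = "no_hepatic_no_neuromuscular"                # N0-H0
    UNCLASSIFIABLE = "unclassifiable"


ESTABLISHED_SUBTYPES = frozenset(
    {
        SubtypeCategory.PERINATAL_CONGENITAL_NEUROMUSCULAR,
        SubtypeCategory.JUVENILE_NEUROMUSCULAR,
        SubtypeCategory.CLASSIC_HEPATIC,
        SubtypeCategory.NON_PROGRESSIVE_HEPATIC,
    }
)

ESTABLISHED_COMBINATIONS = frozenset(
    {(NScore.N3, HScore.H0), (NScore.N1, HScore.H0),
     (NScore.N0, HScore.H3), (NScore.N0, HScore.H1)}
)


@dataclass(frozen=True)
class PhenotypeScore:
    """Two-part score; ``complete`` iff neither component is unscorable."""

    n: NScore
    h: HScore

    @property
    def complete(self) -> bool:
        return self.n is not NScore.UNSCORABLE and self.h is not HScore.UNSCORABLE

    def __str__(self) -> str:
        return f"{self.n.value}-{self.h.value}"


_SEVERE_ALWAYS = {
    ClinicalFinding.LIVER_FAILURE,
    ClinicalFinding.HEPATIC_SYNTHETIC_DYSFUNCTION,
    ClinicalFinding.JAUNDICE,
    ClinicalFinding.HYPERBILIRUBINEMIA,
    ClinicalFinding.ASCITES,
    ClinicalFinding.VARICES,
    ClinicalFinding.GI_BLEED,
}


def has_severe_hepatic_features(record: PatientRecord) -> bool:
    """True iff the record carries at least one severe hepatic feature.

    Qualifying findings only: newborn-period hyperbilirubinemia and
    heart-failure ascites are excluded upstream.  Splenomegaly is severe only
    with a documented platelet count below 150,000/ul.
    """
    for obs in qualifying_findings(record, BodySystem.HEPATIC):
        if obs.code in _SEVERE_ALWAYS:
            return True
        if (
            obs.code is ClinicalFinding.SPLENOMEGALY
            and obs.platelet_count is not None
            and obs.platelet_count < THROMBOCYTOPENIA_THRESHOLD
        ):
            return True
    return False


def _documented_survival_months(record: PatientRecord) -> Optional[float]:
    """Greatest age (months) the patient is documented to have reached.

    Death age, last follow-up and transplant age all document survival to
    that age.  None if no age is documented.
    """
    ages = [
        a
        for a in (
            record.age_at_death_months,
            record.age_at_last_followup_months,
            record.age_at_transplant_months,
        )
        if a is not None
    ]
    return max(ages) if ages else None


def _check_not_prenatal(record: PatientRecord) -> None:
    if record.prenatal_death:
        raise PrenatalDeathError(
            f"{record.patient_id}: patients who died in utero are not scored"
        )


def score_neuromuscular(record: PatientRecord, involvement: InvolvementStatus) -> NScore:
    """Score the neuromuscular component given the involvement status."""
    _check_not_prenatal(record)
    if involvement is InvolvementStatus.ABSENT:
        return NScore.N0
    if involvement is InvolvementStatus.UNKNOWN:
        return NScore.UNSCORABLE
    onset = record.neuromuscular_onset
    if onset.value == "postnatal":
        return NScore.N1
    if onset.value in ("prenatal", "at_birth"):
        if (
            record.vital_status is VitalStatus.DECEASED
            and record.age_at_death_months is not None
            and record.age_at_death_months < NEONATAL_CUTOFF_MONTHS
        ):
            return NScore.N3
        survived = _documented_survival_months(record)
        if survived is not None and survived >= NEONATAL_CUTOFF_MONTHS:
            return NScore.N2
        return NScore.UNSCORABLE  # censored before the 6-month cutoff
    # involvement present but onset unreported (or "none_reported", which
    # contradicts presence): refuse to guess
    return NScore.UNSCORABLE


def score_hepatic(
    record: PatientRecord,
    involvement: InvolvementStatus,
    *,
    require_hepatic_death_attribution: bool = False,
) -> HScore:
    """Score the hepatic component given the involvement status.

    With ``require_hepatic_death_attribution=True``, a death before 5 years
    counts toward H3 only when ``death_attributed_hepatic`` is true
    (transplant before 5 years always counts).
    """
    _check_not_prenatal(record)
    if involvement is InvolvementStatus.ABSENT:
        return HScore.H0
    if involvement is InvolvementStatus.UNKNOWN:
        return HScore.UNSCORABLE
    if not has_severe_hepatic_features(record):
        return HScore.H1
    # severe features: outcome decides H2 vs H3
    lt_age = record.age_at_transplant_months
    if (
        record.liver_transplant is TransplantStatus.YES
        and lt_age is not None
        and lt_age < HEPATIC_CUTOFF_MONTHS
    ):
        return HScore.H3
    if (
        record.vital_status is VitalStatus.DECEASED
        and record.age_at_death_months is not None
        and record.age_at_death_months < HEPATIC_CUTOFF_MONTHS
    ):
        death_counts = (
            not require_hepatic_death_attribution
            or record.death_attributed_hepatic is True
        )
        if death_counts:
            return HScore.H3
    survived = _documented_survival_months(record)
    if survived is not None and survived >= HEPATIC_CUTOFF_MONTHS:
        # survival to >=5 years; H2 requires no transplant before 60 months,
        # so an undetermined transplant history leaves the score open
        if record.liver_transplant is TransplantStatus.NO:
            return HScore.H2
        if (
            record.liver_transplant is TransplantStatus.YES
            and lt_age is not None
            and lt_age >= HEPATIC_CUTOFF_MONTHS
        ):
            return HScore.H2
        return HScore.UNSCORABLE
    return HScore.UNSCORABLE  # alive (or undocumented) below the 5-year cutoff


def assign_phenotype_score(
    record: PatientRecord,
    profile: Optional[InvolvementProfile] = None,
    *,
    require_hepatic_death_attribution: bool = False,
) -> PhenotypeScore:
    """Assess involvement (unless a profile is supplied) and score both
    components."""
    _check_not_prenatal(record)
    if profile is None:
        profile = assess_profile(record)
    n = score_neuromuscular(record, profile.neuromuscular)
    h = score_hepatic(
        record,
        profile.hepatic,
        require_hepatic_death_attribution=require_hepatic_death_attribution,
    )
    return PhenotypeScore(n=n, h=h)


def classify_subtype(score: PhenotypeScore) -> SubtypeCategory:
    """Total, single-valued mapping from a two-part score to its category."""
    if not score.complete:
        return SubtypeCategory.UNCLASSIFIABLE
    n, h = score.n.rank, score.h.rank
    assert n is not None and h is not None
    if n > 0 and h > 0:
        return SubtypeCategory.MIXED
    if (score.n, score.h) == (NScore.N3, HScore.H0):
        return SubtypeCategory.PERINATAL_CONGENITAL_NEUROMUSCULAR
    if (score.n, score.h) == (NScore.N2, HScore.H0):
        return SubtypeCategory.INTERMEDIATE_NEUROMUSCULAR
    if (score.n, score.h) == (NScore.N1, HScore.H0):
        return SubtypeCategory.JUVENILE_NEUROMUSCULAR
    if (score.n, score.h) == (NScore.N0, HScore.H3):
        return SubtypeCategory.CLASSIC_HEPATIC
    if (score.n, score.h) == (NScore.N0, HScore.H2):
        return SubtypeCategory.INTERMEDIATE_HEPATIC
    if (score.n, score.h) == (NScore.N0, HScore.H1):
        return SubtypeCategory.NON_PROGRESSIVE_HEPATIC
    return SubtypeCategory.NO_HEPATIC_NO_NEUROMUSCULAR  # N0-H0
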