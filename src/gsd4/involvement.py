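"""Tri-system involvement assessment.

Each of the three systems affected in youth-onset GSD IV — hepatic,
neuromuscular, cardiac — is classified *present*, *absent* or *unknown*:

* present — at least one qualifying finding for the system survives the
  exclusion rules (hypoglycemia/hyperbilirubinemia limited to the immediate
  newborn period and ascites occurring only in heart failure do not count
  toward hepatic involvement; non-qualifying neurological and structural
  cardiac codes never count);
* absent — no qualifying finding AND the original authors explicitly stated
  normality for the system (the ``explicit_normal_*`` flag);
* unknown — otherwise.  Silence is never treated as absence.

Patients who died in utero are not assessed; passing one is a usage error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .records import (
    BodySystem,
    PatientRecord,
    qualifying_findings,
)

__all__ = [
    "InvolvementStatus",
    "InvolvementProfile",
    "VennCategory",
    "PrenatalDeathError",
    "assess_hepatic",
    "assess_neuromuscular",
    "assess_cardiac",
    "assess_profile",
    "venn_category",
]


class InvolvementStatus(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class VennCategory(str, enum.Enum):
    """Multisystem-involvement category for tri-assessable patients."""

    HEPATIC_ONLY = "hepatic_only"
    NEUROMUSCULAR_ONLY = "neuromuscular_only"
    CARDIAC_ONLY = "cardiac_only"
    HEPATIC_NEUROMUSCULAR = "hepatic_neuromuscular"
    HEPATIC_CARDIAC = "hepatic_cardiac"
    NEUROMUSCULAR_CARDIAC = "neuromuscular_cardiac"
    ALL_THREE = "all_three"
    NONE_INVOLVED = "none_involved"
    NOT_ASSESSABLE = "not_assessable"


@dataclass(frozen=True)
class InvolvementProfile:
    hepatic: InvolvementStatus
    neuromuscular: InvolvementStatus
    cardiac: InvolvementStatus

    def is_tri_assessable(self) -> bool:
        """All three statuses determinable (no unknown)."""
        return InvolvementStatus.UNKNOWN not in (
            self.hepatic, self.neuromuscular, self.cardiac
        )


class PrenatalDeathError(ValueError):
    """Raised when a prenatal-death record reaches assessment or scoring."""


def _check_not_prenatal(record: PatientRecord) -> None:
    if record.prenatal_death:
        raise PrenatalDeathError(
            f"{record.patient_id}: patients who died in utero are not assessed or scored"
        )


def _assess(record: PatientRecord, system: BodySystem, explicit_normal: bool) -> InvolvementStatus:
    _check_not_prenatal(record)
    if qualifying_findings(record, system):
        return InvolvementStatus.PRESENT
    if explicit_normal:
        return InvolvementStatus.ABSENT
    return InvolvementStatus.UNKNOWN


def assess_hepatic(record: PatientRecord) -> InvolvementStatus:
    """Hepatic involvement: organomegaly, portal-hypertension signs, or
    laboratory abnormalities (ALT/GGT/ALP, PT/INR, bilirubin, albumin,
    fasting hypoglycemia), after the newborn-period and heart-failure
    exclusions."""
    return _assess(record, BodySystem.HEPATIC, record.explicit_normal_hepatic)


def assess_neuromuscular(record: PatientRecord) -> InvolvementStatus:
    """Neuromuscular involvement: contractures, ventilator-dependent
    respiratory weakness, hypotonia, hyporeflexia, atrophy/hypotrophy,
    abnormal motor development, abnormal EMG/NCV, or weakness/exercise
    intolerance.  ``other_neurological`` codes are ignored."""
    return _assess(record, BodySystem.NEUROMUSCULAR, record.explicit_normal_neuromuscular)


def assess_cardiac(record: PatientRecord) -> InvolvementStatus:
    """Cardiac involvement: cardiomyopathy, systolic dysfunction, cardiac
    hypertrophy, cardiomegaly, or conduction defects.
    ``structural_cardiac_defect`` codes are ignored."""
    return _assess(record, BodySystem.CARDIAC, record.explicit_normal_cardiac)


def assess_profile(record: PatientRecord) -> InvolvementProfile:
    """Assess all three systems at once."""
    return InvolvementProfile(
        hepatic=assess_hepatic(record),
        neuromuscular=assess_neuromuscular(record),
        cardiac=assess_cardiac(record),
    )


_PATTERN_TO_VENN = {
    (True, True, True): VennCategory.ALL_THREE,
    (True, True, False): VennCategory.HEPATIC_NEUROMUSCULAR,
    (True, False, True): VennCategory.HEPATIC_CARDIAC,
    (False, True, True): VennCategory.NEUROMUSCULAR_CARDIAC,
    (True, False, False): VennCategory.HEPATIC_ONLY,
    (False, True, False): VennCategory.NEUROMUSCULAR_ONLY,
    (False, False, True): VennCategory.CARDIAC_ONLY,
    (False, False, False): VennCategory.NONE_INVOLVED,
}


def venn_category(profile: InvolvementProfile) -> VennCategory:
    """Map an involvement profile to its Venn category.

    Defined for all 27 status triples: any unknown yields ``not_assessable``;
    the eight fully determined patterns map to their present/absent
    combination.
    """
    if not profile.is_tri_assessable():
        return VennCategory.NOT_ASSESSABLE
    key = (
        profile.hepatic is InvolvementStatus.PRESENT,
        profile.neuromuscular is InvolvementStatus.PRESENT,
        profile.cardiac is InvolvementStatus.PRESENT,
    )
    return _PATTERN_TO_VENN[key]
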