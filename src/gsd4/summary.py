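"""Cohort-level aggregation: score matrix, Venn distribution, prevalence,
survival clusters, and a combined report.

Conventions
-----------
* Prenatal deaths are excluded from assessment, scoring and prevalence
  denominators; they form their own bin in the survival summary.
* Death ages are binned twice: once into clean half-open bins
  (``lt_6mo`` = [0, 6) months, ``mo6_to_lt4y`` = [6, 48) months,
  ``ge_4y`` = [48, inf)) and once into the descriptive literature-style bins
  (0-4 months, 6 months-3 years, after 4 years), whose gaps — (4, 6) months
  and (36, 48] months — fall into an explicit ``other`` bin so no death can
  silently vanish.  Deaths at an unknown age are tallied under
  ``unknown_age`` in both mappings.
* Percentages render half-up at one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .involvement import (
    InvolvementStatus,
    VennCategory,
    assess_cardiac,
    assess_hepatic,
    assess_neuromuscular,
    assess_profile,
    venn_category,
)
from .records import Cohort, PatientRecord, VitalStatus
from .scoring import (
    ESTABLISHED_COMBINATIONS,
    HScore,
    NScore,
    PhenotypeScore,
    SubtypeCategory,
    assign_phenotype_score,
    classify_subtype,
)

__all__ = [
    "ScoreMatrix",
    "VennSummary",
    "SurvivalSummary",
    "CohortReport",
    "score_matrix",
    "subtype_consistency_fraction",
    "venn_summary",
    "involvement_prevalence",
    "survival_summary",
    "build_report",
    "percent",
]

COMPLETE_N = (NScore.N0, NScore.N1, NScore.N2, NScore.N3)
COMPLETE_H = (HScore.H0, HScore.H1, HScore.H2, HScore.H3)

ASSESSABLE_VENN = (
    VennCategory.HEPATIC_ONLY,
    VennCategory.NEUROMUSCULAR_ONLY,
    VennCategory.CARDIAC_ONLY,
    VennCategory.HEPATIC_NEUROMUSCULAR,
    VennCategory.HEPATIC_CARDIAC,
    VennCategory.NEUROMUSCULAR_CARDIAC,
    VennCategory.ALL_THREE,
    VennCategory.NONE_INVOLVED,
)

SINGLE_SYSTEM = (
    VennCategory.HEPATIC_ONLY,
    VennCategory.NEUROMUSCULAR_ONLY,
    VennCategory.CARDIAC_ONLY,
)
TWO_SYSTEM = (
    VennCategory.HEPATIC_NEUROMUSCULAR,
    VennCategory.HEPATIC_CARDIAC,
    VennCategory.NEUROMUSCULAR_CARDIAC,
)


def percent(numerator: int, denominator: int) -> float:
    """Percentage rendered half-up at one decimal (e.g. 32/82 -> 39.0)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for a zero denominator")
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _postnatal(cohort: Cohort) -> list[PatientRecord]:
    return [p for p in cohort.patients if not p.prenatal_death]


@dataclass(frozen=True)
class ScoreMatrix:
    """Counts of complete (N, H) score combinations.

    ``n_scored`` complete two-part scores; ``n_unscored`` patients (prenatal
    deaths excluded) with at least one unscorable component.
    """

    counts: dict[tuple[NScore, HScore], int]
    n_scored: int
    n_unscored: int

    def count(self, n: NScore, h: HScore) -> int:
        return self.counts.get((n, h), 0)

    @property
    def n_established(self) -> int:
        return sum(self.counts.get(cell, 0) for cell in ESTABLISHED_COMBINATIONS)

    @property
    def n_mixed(self) -> int:
        return sum(
            c for (n, h), c in self.counts.items() if n.rank > 0 and h.rank > 0
        )


def score_matrix(cohort: Cohort, *, require_hepatic_death_attribution: bool = False) -> ScoreMatrix:
    """Score every non-prenatal patient and tabulate complete combinations."""
    counts: dict[tuple[NScore, HScore], int] = {}
    n_scored = n_unscored = 0
    for rec in _postnatal(cohort):
        s = assign_phenotype_score(
            rec, require_hepatic_death_attribution=require_hepatic_death_attribution
        )
        if s.complete:
            n_scored += 1
            counts[(s.n, s.h)] = counts.get((s.n, s.h), 0) + 1
        else:
            n_unscored += 1
    return ScoreMatrix(counts=counts, n_scored=n_scored, n_unscored=n_unscored)


def subtype_consistency_fraction(matrix: ScoreMatrix) -> float:
    """Fraction of scored patients in one of the four established-subtype
    cells (N3-H0, N1-H0, N0-H3, N0-H1)."""
    if matrix.n_scored == 0:
        raise ZeroDivisionError(
            "subtype consistency undefined: no patients with a complete score"
        )
    return matrix.n_established / matrix.n_scored


@dataclass(frozen=True)
class VennSummary:
    counts: dict[VennCategory, int]
    n_assessable: int
    n_not_assessable: int

    def count(self, cat: VennCategory) -> int:
        return self.counts.get(cat, 0)

    @property
    def n_single_system(self) -> int:
        return sum(self.counts.get(c, 0) for c in SINGLE_SYSTEM)

    @property
    def n_two_system(self) -> int:
        return sum(self.counts.get(c, 0) for c in TWO_SYSTEM)


def venn_summary(cohort: Cohort) -> VennSummary:
    """Venn-category counts over tri-assessable, non-prenatal patients."""
    counts: dict[VennCategory, int] = {}
    n_assessable = n_not = 0
    for rec in _postnatal(cohort):
        cat = venn_category(assess_profile(rec))
        if cat is VennCategory.NOT_ASSESSABLE:
            n_not += 1
        else:
            n_assessable += 1
            counts[cat] = counts.get(cat, 0) + 1
    return VennSummary(counts=counts, n_assessable=n_assessable, n_not_assessable=n_not)


_ASSESSORS = {
    "hepatic": assess_hepatic,
    "neuromuscular": assess_neuromuscular,
    "cardiac": assess_cardiac,
}


def involvement_prevalence(cohort: Cohort, system: str) -> dict:
    """Prevalence of involvement of one system among assessable patients.

    Returns ``{"n_assessable", "n_present", "fraction"}``; the fraction is
    None (flagged) when no patient is assessable.
    """
    if system not in _ASSESSORS:
        raise ValueError(f"unknown system {system!r}; expected one of {sorted(_ASSESSORS)}")
    assess = _ASSESSORS[system]
    n_assessable = n_present = 0
    for rec in _postnatal(cohort):
        status = assess(rec)
        if status is InvolvementStatus.UNKNOWN:
            continue
        n_assessable += 1
        if status is InvolvementStatus.PRESENT:
            n_present += 1
    fraction = (n_present / n_assessable) if n_assessable else None
    return {"n_assessable": n_assessable, "n_present": n_present, "fraction": fraction}


_DEATH_BIN_KEYS = ("prenatal", "lt_6mo", "mo6_to_lt4y", "ge_4y", "unknown_age")
_PAPER_BIN_KEYS = ("prenatal", "mo0_4", "mo6_y3", "gt_y4", "other", "unknown_age")


@dataclass(frozen=True)
class SurvivalSummary:
    n_known_status: int
    n_alive: int
    n_deceased: int
    death_bins: dict[str, int] = field(default_factory=dict)
    paper_bins: dict[str, int] = field(default_factory=dict)


def _clean_bin(age: Optional[float]) -> str:
    if age is None:
        return "unknown_age"
    if age < 6:
        return "lt_6mo"
    if age < 48:
        return "mo6_to_lt4y"
    return "ge_4y"


def _descriptive_bin(age: Optional[float]) -> str:
    if age is None:
        return "unknown_age"
    if age <= 4:
        return "mo0_4"
    if 6 <= age <= 36:
        return "mo6_y3"
    if age > 48:
        return "gt_y4"
    return "other"  # the gap intervals (4, 6) months and (36, 48] months


def survival_summary(cohort: Cohort) -> SurvivalSummary:
    """Vital-status counts and death-timing bins.

    Denominator for alive/deceased is patients with known status.  Prenatal
    deaths form their own bin; deceased patients with no recorded age are
    tallied under ``unknown_age``.
    """
    death_bins = {k: 0 for k in _DEATH_BIN_KEYS}
    paper_bins = {k: 0 for k in _PAPER_BIN_KEYS}
    n_alive = n_deceased = 0
    for rec in cohort.patients:
        if rec.vital_status is VitalStatus.ALIVE:
            n_alive += 1
        elif rec.vital_status is VitalStatus.DECEASED:
            n_deceased += 1
            if rec.prenatal_death:
                death_bins["prenatal"] += 1
                paper_bins["prenatal"] += 1
            else:
                age = rec.age_at_death_months
                death_bins[_clean_bin(age)] += 1
                paper_bins[_descriptive_bin(age)] += 1
    return SurvivalSummary(
        n_known_status=n_alive + n_deceased,
        n_alive=n_alive,
        n_deceased=n_deceased,
        death_bins=death_bins,
        paper_bins=paper_bins,
    )


@dataclass(frozen=True)
class CohortReport:
    """All cohort summaries plus per-patient scores, with renderers."""

    n_patients: int
    n_prenatal_deaths: int
    score_matrix: ScoreMatrix
    venn: VennSummary
    survival: SurvivalSummary
    prevalence: dict[str, dict]
    subtype_consistency: dict

    def to_dict(self) -> dict:
        sm = self.score_matrix
        matrix_counts = {
            f"{n.value}-{h.value}": sm.count(n, h)
            for n in COMPLETE_N
            for h in COMPLETE_H
        }
        venn_counts = {c.value: self.venn.count(c) for c in ASSESSABLE_VENN}
        prevalence = {}
        for system, p in self.prevalence.items():
            prevalence[system] = {
                "n_assessable": p["n_assessable"],
                "n_present": p["n_present"],
                "fraction": p["fraction"],
                "percent": (
                    percent(p["n_present"], p["n_assessable"])
                    if p["n_assessable"]
                    else None
                ),
            }
        sv = self.survival
        return {
            "n_patients": self.n_patients,
            "n_prenatal_deaths": self.n_prenatal_deaths,
            "score_matrix": {
                "counts": matrix_counts,
                "n_scored": sm.n_scored,
                "n_unscored": sm.n_unscored,
                "n_established": sm.n_established,
                "n_mixed": sm.n_mixed,
            },
            "subtype_consistency": dict(self.subtype_consistency),
            "venn": {
                "counts": venn_counts,
                "n_assessable": self.venn.n_assessable,
                "n_not_assessable": self.venn.n_not_assessable,
                "n_single_system": self.venn.n_single_system,
                "n_two_system": self.venn.n_two_system,
            },
            "prevalence": prevalence,
            "survival": {
                "n_known_status": sv.n_known_status,
                "n_alive": sv.n_alive,
                "n_deceased": sv.n_deceased,
                "percent_alive": (
                    percent(sv.n_alive, sv.n_known_status) if sv.n_known_status else None
                ),
                "percent_deceased": (
                    percent(sv.n_deceased, sv.n_known_status) if sv.n_known_status else None
                ),
                "death_bins": dict(sv.death_bins),
                "paper_style_bins": dict(sv.paper_bins),
            },
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True) + "\n"

    def to_markdown(self) -> str:
        d = self.to_dict()
        sm = self.score_matrix
        lines: list[str] = []
        lines.append("# Cohort phenotype report")
        lines.append("")
        lines.append(f"Patients: {self.n_patients} "
                     f"(prenatal deaths: {self.n_prenatal_deaths})")
        lines.append("")
        lines.append("## Two-part score matrix")
        lines.append("")
        lines.append(f"Complete scores: {sm.n_scored}; unscorable: {sm.n_unscored}")
        lines.append("")
        header = "| N \\ H | " + " | ".join(h.value for h in COMPLETE_H) + " |"
        lines.append(header)
        lines.append("|" + "---|" * 5)
        for n in reversed(COMPLETE_N):
            row = [str(sm.count(n, h)) for h in COMPLETE_H]
            lines.append(f"| {n.value} | " + " | ".join(row) + " |")
        lines.append("")
        if sm.n_scored:
            pe = percent(sm.n_established, sm.n_scored)
            lines.append(
                f"Established-subtype combinations: {sm.n_established}/{sm.n_scored} "
                f"({pe}%); other combinations: {sm.n_scored - sm.n_established} "
                f"({percent(sm.n_scored - sm.n_established, sm.n_scored)}%), "
                f"of which mixed (N>0 and H>0): {sm.n_mixed}"
            )
        else:
            lines.append("Established-subtype fraction undefined (no scored patients).")
        lines.append("")
        lines.append("## Multisystem involvement (tri-assessable patients)")
        lines.append("")
        lines.append(f"Tri-assessable: {self.venn.n_assessable}; "
                     f"not assessable: {self.venn.n_not_assessable}")
        lines.append("")
        lines.append("| Category | n | % of assessable |")
        lines.append("|---|---|---|")
        for cat in ASSESSABLE_VENN:
            c = self.venn.count(cat)
            pct = percent(c, self.venn.n_assessable) if self.venn.n_assessable else "-"
            lines.append(f"| {cat.value} | {c} | {pct} |")
        lines.append("")
        lines.append("## Per-system prevalence")
        lines.append("")
        lines.append("| System | present | assessable | % |")
        lines.append("|---|---|---|---|")
        for system, p in d["prevalence"].items():
            pct = p["percent"] if p["percent"] is not None else "undefined"
            lines.append(
                f"| {system} | {p['n_present']} | {p['n_assessable']} | {pct} |"
            )
        lines.append("")
        lines.append("## Survival")
        lines.append("")
        sv = d["survival"]
        if sv["n_known_status"]:
            lines.append(
                f"Known vital status: {sv['n_known_status']} "
                f"(alive {sv['n_alive']} = {sv['percent_alive']}%, "
                f"deceased {sv['n_deceased']} = {sv['percent_deceased']}%)"
            )
        else:
            lines.append("No patients with known vital status.")
        lines.append("")
        lines.append("| Death timing | n | % of deaths |")
        lines.append("|---|---|---|")
        for key in _PAPER_BIN_KEYS:
            c = sv["paper_style_bins"][key]
            pct = percent(c, sv["n_deceased"]) if sv["n_deceased"] else "-"
            lines.append(f"| {key} | {c} | {pct} |")
        lines.append("")
        return "\n".join(lines)

    def matrix_tsv(self) -> str:
        """Score matrix as TSV (rows N3..N0, columns H0..H3)."""
        out = ["N\\H\t" + "\t".join(h.value for h in COMPLETE_H)]
        for n in reversed(COMPLETE_N):
            out.append(
                n.value + "\t" + "\t".join(str(self.score_matrix.count(n, h)) for h in COMPLETE_H)
            )
        return "\n".join(out) + "\n"


def build_report(cohort: Cohort, *, require_hepatic_death_attribution: bool = False) -> CohortReport:
    """Compose all summaries into one deterministic report."""
    matrix = score_matrix(
        cohort, require_hepatic_death_attribution=require_hepatic_death_attribution
    )
    if matrix.n_scored:
        consistency = {
            "n_consistent": matrix.n_established,
            "n_scored": matrix.n_scored,
            "fraction": matrix.n_established / matrix.n_scored,
            "percent": percent(matrix.n_established, matrix.n_scored),
        }
    else:
        consistency = {
            "n_consistent": 0, "n_scored": 0, "fraction": None, "percent": None,
        }
    return CohortReport(
        n_patients=len(cohort.patients),
        n_prenatal_deaths=sum(1 for p in cohort.patients if p.prenatal_death),
        score_matrix=matrix,
        venn=venn_summary(cohort),
        survival=survival_summary(cohort),
        prevalence={s: involvement_prevalence(cohort, s) for s in _ASSESSORS},
        subtype_consistency=consistency,
    )


def per_patient_table(
    cohort: Cohort, *, require_hepatic_death_attribution: bool = False
):
    """Per-patient involvement, scores and subtype as a pandas DataFrame.

    Prenatal deaths appear with empty assessment fields.
    """
    import pandas as pd

    rows = []
    for rec in cohort.patients:
        if rec.prenatal_death:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "prenatal_death": True,
                    "hepatic": "", "neuromuscular": "", "cardiac": "",
                    "venn_category": "", "n_score": "", "h_score": "",
                    "score": "", "subtype": "",
                }
            )
            continue
        profile = assess_profile(rec)
        s = assign_phenotype_score(
            rec, profile, require_hepatic_death_attribution=require_hepatic_death_attribution
        )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "prenatal_death": False,
                "hepatic": profile.hepatic.value,
                "neuromuscular": profile.neuromuscular.value,
                "cardiac": profile.cardiac.value,
                "venn_category": venn_category(profile).value,
                "n_score": s.n.value,
                "h_score": s.h.value,
                "score": str(s),
                "subtype": classify_subtype(s).value,
            }
        )
    return pd.DataFrame(rows)
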