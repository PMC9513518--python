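# Methods

## The characterization model

GSD IV presentations vary along (at least) three partially independent
dimensions — hepatic, neuromuscular and cardiac disease — and the package
treats phenotype as a point in that space rather than as membership in one
of the four traditional subtypes. The procedure is deliberately rule-based
and descriptive: no parameters are estimated, and every output is a count or
a ratio of counts over an explicitly defined denominator. The interesting
methodological content is in the rules and, above all, in the handling of
missing information.

### Tri-state involvement logic

Case data (particularly literature-extracted case data) are radically
incomplete, so each system's involvement is a three-valued variable:

* **present** — at least one qualifying coded finding survives the
  exclusion rules. Exclusions: hypoglycemia and/or hyperbilirubinemia
  limited to the immediate newborn period, and ascites occurring
  exclusively in heart failure, are not used for hepatic characterization;
  neurological findings not clearly attributable to GSD IV (epilepsy,
  isolated language delay) and structural cardiac defects (VSD, double
  aortic arch) never qualify. Excluded findings are stored for provenance
  but prove nothing in either direction.
* **absent** — no qualifying finding *and* the source explicitly stated
  normality for that system (the `explicit_normal_*` flags). This is the
  load-bearing convention: absence is an affirmative datum, and a record
  with no hepatic information is *unknown*, not hepatically normal.
* **unknown** — otherwise. Unknown propagates: a patient with any unknown
  system is excluded from the Venn denominator (`not_assessable`), and an
  unknown-involvement component makes the two-part score incomplete.

Patients who died in utero are never assessed or scored; passing one to an
assessment function raises an error rather than silently returning unknown,
because doing so indicates a caller bug.

### Score semantics and boundaries

The N component combines onset timing with survival; the H component
combines severity (the severe-feature list, with splenomegaly qualifying
only with documented platelets <150,000/µl — the conventional threshold for
definite clinically evident portal hypertension) with transplant-free
survival to age 5. Conventions, chosen once and applied everywhere:

* Cutoffs are strict on the death side and inclusive on the survival side:
  death at exactly 6 months is survival to ≥6 months (N2, not N3); death at
  exactly 60 months is survival to ≥5 years (H2, not H3). Five years is
  operationalized as exactly 60 months; all ages are months (decimals
  allowed).
* Documented survival to age *a* is evidenced by death at *a*, last
  follow-up at *a*, or transplant at *a* (whichever is greatest).
* Censoring is conservative: a patient alive below a cutoff their score
  depends on is **unscorable** for that component, never optimistically
  assigned the milder grade. Likewise a severe-hepatic patient surviving
  past 5 years with an *undetermined* transplant history cannot be H2
  (H2 asserts the absence of an early transplant).
* A patient with neuromuscular involvement whose onset timing is unreported
  is unscorable on N — the rules refuse to guess.
* Hyperbilirubinemia of any magnitude counts as a severe feature unless
  limited to the newborn period; the source material gives no magnitude
  threshold, and inventing one would be less reproducible than counting all.
* H3 does not require the death to be hepatic-caused; the
  `require_hepatic_death_attribution` switch (library keyword and CLI flag)
  restricts H3 deaths to those with `death_attributed_hepatic=true` for
  sensitivity analyses. The default is off because attribution is rarely
  recorded and, empirically, patients dying young of neuromuscular disease
  do not carry severe hepatic features.

The subtype map is total over the 5×5 component grid (four grades plus
unscorable per axis): the four established subtypes are exactly the cells
N3-H0, N1-H0, N0-H3, N0-H1; N2-H0 and N0-H2 are intermediate; any N>0∧H>0
cell is mixed; N0-H0 is the exclusively-cardiac corner; any incomplete score
is unclassifiable. Both this map and the Venn map are verified by exhaustive
enumeration against independently written decision tables, and the whole
scoring path is checked against an independent flat re-derivation on
thousands of randomized records.

### Summary conventions

* Percentages render half-up at one decimal (`Decimal`-based, so 0.05%
  becomes 0.1%), matching the convention of the descriptive literature.
* Every denominator is reported next to its numerator, and the report
  recomputes percentages from counts on demand — there is no cached value
  to drift.
* Death timing is binned twice: clean half-open bins ([0, 6) months,
  [6, 48) months, [48, ∞)) for analysis, and the descriptive bins used in
  the case literature (0–4 months, 6 months–3 years, after 4 years), whose
  gap intervals — (4, 6) months and (36, 48] months — go to an explicit
  `other` bin. Deaths at an unknown age get their own tally in both
  mappings, so each bin mapping always sums to the number of deaths.
* The alive/deceased split is computed over patients with *known* vital
  status, not over the whole cohort.

## The synthetic-cohort generator

`generate_cohort` is an inverse of the scoring pipeline: a cohort spec lists
cell groups — a count, an (N, H, cardiac) cell key, optionally an outcome
override — and each group is realized with the minimal sufficient finding
set (one qualifying finding per involved system, explicit-normal flags for
uninvolved ones) and an outcome drawn strictly inside the age interval the
cell requires. Design choices:

* **Self-verification.** Every generated record is re-scored through the
  real pipeline; if it does not recover its requested cell the generator
  raises instead of emitting it. Parameter recovery under zero missingness
  is therefore exact by construction, and tests confirm it over randomized
  specs.
* **Boundary avoidance.** Ages are drawn in tenths of a month strictly
  inside the open interval, so generated cohorts are insensitive to the
  boundary conventions above.
* **Unscorable flavours.** `"N*"`/`"H*"` request involvement that is present
  but unscorable (unreported onset; severe features censored before the
  5-year cutoff); `"N?"`/`"H?"` request unknown involvement. Both are
  first-class cells, since realistic cohorts are full of them.
* **One genuinely infeasible region.** N3 (death before 6 months) cannot
  combine with H2 or with the censored-severe flavour `H*` (both require
  surviving toward the 5-year cutoff); such requests raise
  `InfeasibleCellError`. Every other combination is constructible —
  including N3 with severe hepatic features (N3-H3), which is absent from
  observed data but deliberately not hard-coded away.
* **Determinism.** One `numpy` PCG64 generator seeded from the spec; the
  same spec yields byte-identical files on any platform.
* An `embellish` option adds extra *consistent* findings and permutes the
  findings list, for stress-testing permutation invariance.
* `perturb_missingness` independently blanks fields to their unknown states
  at per-field rates. It only removes information (dependent fields are
  cleared together, e.g. death age with vital status), so the number of
  scorable patients is non-increasing — a property the tests check across
  seeds.

### The reference cohort

`reference_cohort()` encodes the aggregate statistics of the published
literature cohort of youth-onset GSD IV as a deterministic 146-patient
synthetic cohort: 19 prenatal deaths; 82 patients with a complete two-part
score distributed as N3-H0=13, N2-H0=3, N1-H0=2, N0-H0=2, N0-H1=10,
N0-H2=3, N0-H3=7 and 42 mixed; 82 tri-assessable patients with Venn counts
14/10/2 (single), 32/3/3 (double), 18 (triple); hepatic and neuromuscular
prevalence 90/110 and 88/110; cardiac prevalence 36/95; 139 known-status
patients with 78 deaths binned 19 prenatal, 35 at 0–4 months, 18 at
6 months–3 years, 6 after 4 years.

Three reconciliations were required where the published aggregates
underdetermine (or overdetermine) a cohort:

1. The 82 tri-assessable and 82 fully-scored patients cannot be the same
   set (the Venn marginals imply 67 hepatic-present and 63
   neuromuscular-present; the score matrix implies 62 and 60). The
   reference cohort overlaps them maximally: 8 patients are tri-assessable
   but unscorable (onset unreported) and 8 are scored but lack cardiac
   data.
2. The cardiac prevalence denominator is not printed. It must be ≥82 and
   reachable by adding patients contributing at most one cardiac-present
   each; the smallest arithmetically and structurally consistent solution
   is 36/95, which the cohort realizes with 13 cardiac-only-assessed
   patients (10 present).
3. The known-vital-status denominator is likewise unprinted; 139 is the
   smallest integer consistent with the printed alive/deceased percentages
   and 78 deaths. Note 19/78 = 24.36%, which rounds to 24.4% at one
   decimal although the source figure prints 24.3%; the counts, not the
   rounded figure, are authoritative here.
4. The mixed-cell breakdown (42 patients across nine N>0∧H>0 cells) is not
   printed; the chosen distribution (20 N1-H1, 12 N3-H1, 4 N1-H3, 3 N2-H3,
   2 N2-H1, 1 N2-H2) follows the qualitative case descriptions: no N3
   patient carries severe hepatic features, seven N2 patients in total,
   and both severe (congenital-neuromuscular + classic-hepatic) and mild
   (juvenile + non-progressive) mixed presentations occur. Only the total
   enters any headline statistic.

The generator emulates exactly the information structure the scoring rules
consume: coded findings, onset categories, vital status and three ages. It
does **not** emulate longitudinal progression, correlated finding batteries,
inter-rater extraction noise, multi-publication reconciliation, genotypes,
or realistic marginal frequencies of individual finding codes. Passing
tests therefore demonstrate that the pipeline's logic is correct and that
the published aggregates are internally reconstructible — not that the
pipeline has been validated against real patient records.

## Problem sizes and runtime

All computations are exact counting over ≤146-patient cohorts. The test
suite uses 2,000 randomized records for the decision-table equivalence
check, 100 randomized specs for parameter recovery, and 100 seeds for the
missingness monotonicity property; the full suite and the acceptance script
each complete in well under a minute on one CPU.

## Known limitations

* One consolidated state per patient: reconciling conflicting reports
  across publications is the user's responsibility upstream.
* The severe-feature rule takes findings at face value (any
  non-newborn-period hyperbilirubinemia counts; no magnitude thresholds
  except the platelet cutoff).
* Ordinal scores are descriptive, not prognostic; the package deliberately
  offers no inference, confidence intervals or prediction.
* The descriptive death-timing bins are reproduced gaps and all; analyses
  should prefer the clean half-open bins.
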