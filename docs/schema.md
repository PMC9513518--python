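# Cohort file schemas

A cohort is a set of patient records with unique `patient_id`s, stored as
CSV (one row per patient) or JSON (a list of objects, or
`{"patients": [...]}`). The JSON form is described machine-readably in
`src/gsd4/data/cohort.schema.json`. Both forms round-trip losslessly
through `read_cohort` / `write_cohort`.

**Missingness convention:** an omitted or empty field always means
*unknown*, never a negative finding. Absence of involvement is recorded
explicitly via the `explicit_normal_*` flags.

## Fields (CSV columns = JSON keys)

| field | type | notes |
|---|---|---|
| `patient_id` | string, required | unique within a cohort |
| `findings` | list | CSV: `;`-separated tokens `code[:qualifier=value]...` |
| `neuromuscular_onset` | `prenatal` \| `at_birth` \| `postnatal` \| `none_reported` \| `unknown` | |
| `vital_status` | `alive` \| `deceased` \| `unknown` | |
| `prenatal_death` | bool | implies `deceased`, excludes a postnatal death age |
| `age_at_death_months` | number ≥0 | requires `deceased` |
| `age_at_last_followup_months` | number ≥0 | |
| `liver_transplant` | `yes` \| `no` \| `unknown` | `yes` requires the age below |
| `age_at_transplant_months` | number ≥0 | |
| `explicit_normal_hepatic` | bool | authors stated hepatic normality |
| `explicit_normal_neuromuscular` | bool | |
| `explicit_normal_cardiac` | bool | |
| `death_attributed_hepatic` | bool, optional | used only with the attribution switch |

All ages are months; decimals allowed.

## Finding codes

Hepatic: `hepatomegaly`, `splenomegaly`, `varices`, `ascites`,
`elevated_alt`, `elevated_ggt`, `elevated_alp`, `prolonged_pt_inr`,
`hyperbilirubinemia`, `low_albumin`, `fasting_hypoglycemia`,
`liver_failure`, `hepatic_synthetic_dysfunction`, `jaundice`, `gi_bleed`.

Neuromuscular: `contractures`, `ventilator_dependent_respiratory_weakness`,
`hypotonia`, `hyporeflexia`, `atrophy_or_hypotrophy`,
`abnormal_motor_development`, `abnormal_emg_or_ncv`,
`weakness_or_exercise_intolerance`.

Cardiac: `cardiomyopathy`, `systolic_dysfunction`, `cardiac_hypertrophy`,
`cardiomegaly`, `conduction_defect`.

Non-qualifying (stored, never counted): `other_neurological`,
`structural_cardiac_defect`.

### Finding qualifiers

| qualifier | applies to | effect |
|---|---|---|
| `newborn_period_only=true` | `fasting_hypoglycemia`, `hyperbilirubinemia` | excluded from hepatic characterization |
| `heart_failure_context_only=true` | `ascites` | excluded from hepatic characterization |
| `platelet_count=<int per µl>` | `splenomegaly` | `<150000` makes splenomegaly a severe feature |
| `age_first_observed_months=<number>` | any | provenance only |

CSV example row:

```
L42,"splenomegaly:platelet_count=120000;hypotonia;cardiomyopathy",at_birth,alive,false,,30,no,,false,false,false,
```

## Simulation spec files

`gsd4 simulate --spec …` and `gsd4.load_spec` accept JSON or YAML:

```yaml
seed: 7
n_prenatal_deaths: 2
cells:
  - {count: 4, n: N3, h: H0, cardiac: absent}
  - count: 3
    n: N1
    h: H1
    cardiac: unknown
    outcome: {vital: deceased, death_age_range: [6.5, 34.5]}
```

Cell keys: `N0`–`N3`/`H0`–`H3` (scored grades), `N*`/`H*` (involvement
present but unscorable), `N?`/`H?` (involvement unknown); cardiac
`present`/`absent`/`unknown`. `survival_profile` adds extra deceased
patients by timing bin; `missingness_rates` blanks fields after generation.
`src/gsd4/data/reference_spec.json` is the complete spec of the built-in
reference cohort.
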