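{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "gsd4 cohort (JSON form)",
 "description": "A cohort is a list of patient record objects. Omitted fields mean 'unknown', never 'absent'. The CSV form has one column per field below, with findings packed as semicolon-separated 'code[:qualifier=value]' tokens; see docs/schema.md.",
 "type": "array",
 "items": {
  "type": "object",
  "additionalProperties": false,
  "required": ["patient_id"],
  "properties": {
   "patient_id": {"type": "string", "minLength": 1},
   "findings": {
    "type": "array",
    "items": {
     "type": "object",
     "additionalProperties": false,
     "required": ["code"],
     "properties": {
      "code": {
       "type": "string",
       "enum": [
        "hepatomegaly", "splenomegaly", "varices", "ascites", "elevated_alt",
        "elevated_ggt", "elevated_alp", "prolonged_pt_inr", "hyperbilirubinemia",
        "low_albumin", "fasting_hypoglycemia", "liver_failure",
        "hepatic_synthetic_dysfunction", "jaundice", "gi_bleed",
        "contractures", "ventilator_dependent_respiratory_weakness", "hypotonia",
        "hyporeflexia", "atrophy_or_hypotrophy", "abnormal_motor_development",
        "abnormal_emg_or_ncv", "weakness_or_exercise_intolerance",
        "cardiomyopathy", "systolic_dysfunction", "cardiac_hypertrophy",
        "cardiomegaly", "conduction_defect",
        "other_neurological", "structural_cardiac_defect"
       ]
      },
      "newborn_period_only": {
       "type": "boolean",
       "description": "Only meaningful for fasting_hypoglycemia/hyperbilirubinemia; excludes the finding from hepatic characterization."
      },
      "heart_failure_context_only": {
       "type": "boolean",
       "description": "Only meaningful for ascites; excludes the finding from hepatic characterization."
      },
      "platelet_count": {"type": "integer", "exclusiveMinimum": 0,
       "description": "Per microliter; qualifies splenomegaly for the severe-feature rule (<150000)."},
      "age_first_observed_months": {"type": "number", "minimum": 0}
     }
    }
   },
   "neuromuscular_onset": {
    "type": "string",
    "enum": ["prenatal", "at_birth", "postnatal", "none_reported", "unknown"]
   },
   "vital_status": {"type": "string", "enum": ["alive", "deceased", "unknown"]},
   "prenatal_death": {"type": "boolean"},
   "age_at_death_months": {"type": "number", "minimum": 0},
   "age_at_last_followup_months": {"type": "number", "minimum": 0},
   "liver_transplant": {"type": "string", "enum": ["yes", "no", "unknown"]},
   "age_at_transplant_months": {"type": "number", "minimum": 0},
   "explicit_normal_hepatic": {"type": "boolean"},
   "explicit_normal_neuromuscular": {"type": "boolean"},
   "explicit_normal_cardiac": {"type": "boolean"},
   "death_attributed_hepatic": {"type": "boolean"}
  }
 }
}
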