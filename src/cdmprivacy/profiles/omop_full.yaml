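# Full OMOP CDM v5.2 privacy classification: 45 PHIs and 17 QIs.
#
# Membership is a best-effort reconstruction of a structural HIPAA review
# of the complete CDM table set (dates/datetimes, sub-state geography,
# provider and device identifiers as PHIs; demographic attributes and
# clinical order codes as QIs). Edit freely for a concrete deployment;
# the 45/17 totals of this shipped document are enforced by validation
# when it is loaded by name ("omop_full").
profile_name: omop_full
cdm_version: "5.2"
variables:
  # --- PHIs: event dates ---------------------------------------------------
  - {table: observation_period, column: observation_period_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: observation_period, column: observation_period_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: specimen, column: specimen_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: death, column: death_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: visit_occurrence, column: visit_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: visit_occurrence, column: visit_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: condition_occurrence, column: condition_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: condition_occurrence, column: condition_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: drug_exposure, column: drug_exposure_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: drug_exposure, column: drug_exposure_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: device_exposure, column: device_exposure_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: device_exposure, column: device_exposure_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: procedure_occurrence, column: procedure_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: measurement, column: measurement_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: observation, column: observation_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: note, column: note_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: note_nlp, column: note_nlp_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: payer_plan_period, column: payer_plan_period_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: payer_plan_period, column: payer_plan_period_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: drug_era, column: drug_era_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: drug_era, column: drug_era_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: dose_era, column: dose_era_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: dose_era, column: dose_era_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: condition_era, column: condition_era_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: condition_era, column: condition_era_end_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: cohort, column: cohort_start_date, role: phi, value_kind: date, mask_rule: year_only}
  - {table: cohort, column: cohort_end_date, role: phi, value_kind: date, mask_rule: year_only}
  # --- PHIs: datetimes -----------------------------------------------------
  - {table: person, column: time_of_birth, role: phi, value_kind: date, mask_rule: year_only}
  - {table: specimen, column: specimen_datetime, role: phi, value_kind: date, mask_rule: year_only}
  - {table: visit_occurrence, column: visit_start_datetime, role: phi, value_kind: date, mask_rule: year_only}
  - {table: visit_occurrence, column: visit_end_datetime, role: phi, value_kind: date, mask_rule: year_only}
  - {table: condition_occurrence, column: condition_start_datetime, role: phi, value_kind: date, mask_rule: year_only}
  - {table: condition_occurrence, column: condition_end_datetime, role: phi, value_kind: date, mask_rule: year_only}
  - {table: drug_exposure, column: drug_exposure_start_datetime, role: phi, value_kind: date, mask_rule: year_only}
  - {table: drug_exposure, column: drug_exposure_end_datetime, role: phi, value_kind: date, mask_rule: year_only}
  # --- PHIs: birth-date parts, geography, identifiers ----------------------
  - {table: person, column: month_of_birth, role: phi, value_kind: code, mask_rule: suppress}
  - {table: person, column: day_of_birth, role: phi, value_kind: code, mask_rule: suppress}
  - {table: location, column: address_1, role: phi, value_kind: geography, mask_rule: suppress}
  - {table: location, column: address_2, role: phi, value_kind: geography, mask_rule: suppress}
  - {table: location, column: city, role: phi, value_kind: geography, mask_rule: suppress}
  - {table: location, column: zip, role: phi, value_kind: geography, mask_rule: suppress}
  - {table: location, column: county, role: phi, value_kind: geography, mask_rule: suppress}
  - {table: provider, column: npi, role: phi, value_kind: identifier, mask_rule: suppress}
  - {table: provider, column: dea, role: phi, value_kind: identifier, mask_rule: suppress}
  - {table: device_exposure, column: unique_device_id, role: phi, value_kind: identifier, mask_rule: suppress}
  # --- QIs: demographic ----------------------------------------------------
  - {table: person, column: year_of_birth, role: qi_demographic, value_kind: year, mask_rule: none}
  - {table: person, column: gender_concept_id, role: qi_demographic, value_kind: code, mask_rule: none}
  - {table: person, column: race_concept_id, role: qi_demographic, value_kind: code, mask_rule: none}
  - {table: person, column: ethnicity_concept_id, role: qi_demographic, value_kind: code, mask_rule: none}
  - {table: location, column: state, role: qi_demographic, value_kind: geography, mask_rule: none}
  # --- QIs: clinical order codes -------------------------------------------
  - {table: condition_occurrence, column: condition_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: procedure_occurrence, column: procedure_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: drug_exposure, column: drug_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: device_exposure, column: device_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: measurement, column: measurement_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: observation, column: observation_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: care_site, column: place_of_service_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: specimen, column: specimen_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: visit_occurrence, column: visit_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: drug_era, column: drug_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: dose_era, column: drug_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
  - {table: condition_era, column: condition_concept_id, role: qi_clinical, value_kind: code, mask_rule: none}
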