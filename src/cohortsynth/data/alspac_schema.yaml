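# Bundled cohort schema: the ALSPAC childhood clinic data dictionary used for
# synthetic data generation. Column names reproduce the published simulated
# variable names verbatim, including their inconsistent BMI capitalisation
# ("BMI" at F@7 but "bmi.17" at TF4) -- do not normalise.
name: alspac-child-clinics
waves:
  - {id: F7, nominal_age_years: 7}
  - {id: F8, nominal_age_years: 8}
  - {id: F9, nominal_age_years: 9}
  - {id: F10, nominal_age_years: 10}
  - {id: F11, nominal_age_years: 11}
  - {id: TF1, nominal_age_years: 12}
  - {id: TF2, nominal_age_years: 13}
  - {id: TF3, nominal_age_years: 15}
  - {id: TF4, nominal_age_years: 17}
columns:
  - {name: sex, source: kz021, kind: sex}
  - {name: height.7, source: f7ms010, kind: height, wave: F7}
  - {name: height.sit.7, source: f7ms012, kind: sitting_height, wave: F7}
  - {name: waist.7, source: f7ms018, kind: waist, wave: F7}
  - {name: hip.7, source: f7ms020, kind: hip, wave: F7}
  - {name: weight.7, source: f7ms026, kind: weight, wave: F7}
  - {name: BMI, source: f7ms026a, kind: bmi, wave: F7}
  - {name: sbp.7, source: f7sa021, kind: sbp, wave: F7}
  - {name: dbp.7, source: f7sa022, kind: dbp, wave: F7}
  - {name: pulse.7, source: f7sa023, kind: pulse, wave: F7}
  - {name: age.7, source: f7003c, kind: age, wave: F7}
  - {name: height.8, source: f8lf020, kind: height, wave: F8}
  - {name: weight.8, source: f8lf021, kind: weight, wave: F8}
  - {name: age.8, source: f8003c, kind: age, wave: F8}
  - {name: height.9, source: f9ms010, kind: height, wave: F9}
  - {name: height.sit.9, source: f9ms012, kind: sitting_height, wave: F9}
  - {name: waist.9, source: f9ms018, kind: waist, wave: F9}
  - {name: hip.9, source: f9ms020, kind: hip, wave: F9}
  - {name: weight.9, source: f9ms026, kind: weight, wave: F9}
  - {name: BMI.9, source: f9ms026a, kind: bmi, wave: F9}
  - {name: sbp.9, source: f9sa021, kind: sbp, wave: F9}
  - {name: dbp.9, source: f9sa022, kind: dbp, wave: F9}
  - {name: pulse.9, source: f9sa023, kind: pulse, wave: F9}
  - {name: age.9, source: f9003c, kind: age, wave: F9}
  - {name: height.10, source: fdms010, kind: height, wave: F10}
  - {name: height.sit.10, source: fdms012, kind: sitting_height, wave: F10}
  - {name: waist.10, source: fdms018, kind: waist, wave: F10}
  - {name: weight.10, source: fdms026, kind: weight, wave: F10}
  - {name: BMI.10, source: fdms026a, kind: bmi, wave: F10}
  - {name: sbp.10, source: SBP, kind: sbp, wave: F10}
  - {name: dbp.10, source: DBP, kind: dbp, wave: F10}
  - {name: age.10, source: fd003c, kind: age, wave: F10}
  - {name: height.11, source: fems010, kind: height, wave: F11}
  - {name: height.sit.11, source: fems012, kind: sitting_height, wave: F11}
  - {name: waist.11, source: fems018, kind: waist, wave: F11}
  - {name: hip.11, source: fems020, kind: hip, wave: F11}
  - {name: weight.11, source: fems026, kind: weight, wave: F11}
  - {name: BMI.11, source: fems026a, kind: bmi, wave: F11}
  - {name: sbp.11, source: fesa021, kind: sbp, wave: F11}
  - {name: dbp.11, source: fesa022, kind: dbp, wave: F11}
  - {name: pulse.11, source: fesa023, kind: pulse, wave: F11}
  - {name: age.11, source: fe003c, kind: age, wave: F11}
  - {name: height.12, source: ff2000, kind: height, wave: TF1}
  - {name: height.sit.12, source: ff2005, kind: sitting_height, wave: TF1}
  - {name: waist.12, source: ff2020, kind: waist, wave: TF1}
  - {name: sbp.12, source: ff2620, kind: sbp, wave: TF1}
  - {name: dbp.12, source: ff2621, kind: dbp, wave: TF1}
  - {name: pulse.12, source: ff2622, kind: pulse, wave: TF1}
  - {name: age.12, source: ff0011a, kind: age, wave: TF1}
  - {name: height.13, source: fg3100, kind: height, wave: TF2}
  - {name: waist.13, source: fg3120, kind: waist, wave: TF2}
  - {name: weight.13, source: fg3130, kind: weight, wave: TF2}
  - {name: sbp.13, source: fg6120, kind: sbp, wave: TF2}
  - {name: dbp.13, source: fg6121, kind: dbp, wave: TF2}
  - {name: pulse.13, source: fg6122, kind: pulse, wave: TF2}
  - {name: age.13, source: fg0011a, kind: age, wave: TF2}
  - {name: height.15, source: fh3000, kind: height, wave: TF3}
  - {name: weight.15, source: fh3010, kind: weight, wave: TF3}
  - {name: waist.15, source: fh4020, kind: waist, wave: TF3}
  - {name: height.sit.15, source: fh4030, kind: sitting_height, wave: TF3}
  - {name: sbp.15, source: fh2030, kind: sbp, wave: TF3}
  - {name: dbp.15, source: fh2031, kind: dbp, wave: TF3}
  - {name: pulse.15, source: fh2032, kind: pulse, wave: TF3}
  - {name: age.15, source: fh0011a, kind: age, wave: TF3}
  - {name: height.17, source: FJMR020, kind: height, wave: TF4}
  - {name: weight.17, source: FJMR022, kind: weight, wave: TF4}
  - {name: sbp.17, source: FJAR020a, kind: sbp, wave: TF4}
  - {name: dbp.17, source: FJAR020b, kind: dbp, wave: TF4}
  - {name: pulse.17, source: FJAR020c, kind: pulse, wave: TF4}
  - {name: bmi.17, source: FJMR022a, kind: bmi, wave: TF4}
  - {name: age.17, source: FJ003a, kind: age, wave: TF4}
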