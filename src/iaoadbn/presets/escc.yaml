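# ESCC-like synthetic cohort preset.
#
# Marginal summary statistics (mean, sd, min, max) of the 17 blood
# indicators, age, and tumor staging category counts of a 298-patient
# esophageal squamous cell carcinoma cohort. Continuous indicators are drawn
# from moment-matched truncated normals; staging columns from the category
# proportions. The binary label survival5y (1 = survived five years or more)
# is planted through a logistic score over the 11 signal indicators below.
#
# The signal coefficients act on per-column z-scores; their signs follow
# clinical direction (later stage, older age, higher coagulation markers ->
# worse survival; higher lymphocyte and red-cell counts -> better survival)
# and their magnitudes are engineering choices. logistic_scale rescales the
# combined score so the cohort's Bayes accuracy is ~0.9.
name: escc
n_patients: 298
target_positive_count: 147
logistic_scale: 5.5
label: survival5y
indicators:
  - {name: BASO, mean: 0.050, sd: 0.118, min: 0.0, max: 1.0}
  - {name: EO, mean: 0.144, sd: 0.272, min: 0.0, max: 3.0}
  - {name: FIB, mean: 379.262, sd: 30.398, min: 167.613, max: 909.725}
  - {name: PTL, mean: 226.289, sd: 7.931, min: 45.0, max: 448.0}
  - {name: ALB, mean: 42.077, sd: 5.005, min: 27.0, max: 59.0}
  - {name: HGB, mean: 137.742, sd: 15.074, min: 95.0, max: 189.0}
  - {name: WBC, mean: 6.564, sd: 2.019, min: 2.18, max: 15.3}
  - {name: MONO, mean: 0.406, sd: 0.301, min: 0.0, max: 1.0}
  - {name: APTT, mean: 35.929, sd: 7.904, min: 15.4, max: 78.5}
  - {name: GLOB, mean: 29.077, sd: 5.122, min: 17.0, max: 45.0}
  - {name: RBC, mean: 4.452, sd: 0.473, min: 2.93, max: 6.04}
  - {name: PT, mean: 10.322, sd: 1.684, min: 7.0, max: 16.5}
  - {name: LYMPH, mean: 1.930, sd: 0.692, min: 0.0, max: 8.0}
  - {name: NEUT, mean: 3.864, sd: 1.682, min: 0.0, max: 10.6}
  - {name: TP, mean: 71.070, sd: 7.209, min: 50.0, max: 92.0}
  - {name: INR, mean: 0.796, sd: 0.185, min: 0.45, max: 1.64}
  - {name: TT, mean: 15.569, sd: 2.575, min: 1.3, max: 46.5}
  # age ~64% of patients at or below 61.5 years, range 38-82
  - {name: Age, mean: 57.5, sd: 11.0, min: 38.0, max: 82.0}
categoricals:
  T_stage: {values: [1, 2, 3, 4], counts: [42, 89, 165, 2]}
  N_stage: {values: [0, 1, 2, 3], counts: [170, 80, 34, 14]}
  TNM_stage: {values: [1, 2, 3, 4], counts: [37, 139, 106, 16]}
signal:
  TNM_stage: -1.2
  BASO: -0.5
  Age: -0.6
  PT: -0.5
  FIB: -0.6
  LYMPH: 0.6
  RBC: 0.5
  TT: -0.4
  PTL: -0.4
  T_stage: -0.8
  GLOB: -0.4
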