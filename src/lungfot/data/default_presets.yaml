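# Default grade presets for the synthetic rejection cohort.
#
# Mechanics entries are lung-level values with every compartment open; the
# sampler multiplies tissue and peripheral-airway parameters by the number of
# compartments when drawing per-compartment values.  Tissue damping G is
# eta*H with hysteresivity eta drawn once per compartment.  Per-animal tissue
# constants scale with the animal's tissue fraction as (TF/tf_ref)^beta.
# Closing pressures Pc (cmH2O) gate compartment participation: a compartment
# contributes only when PEEP >= Pc.
#
# tf_shrink attenuates the within-group part of the TF->mechanics coupling:
# the effective TF driving G,H is tf_mean + tf_shrink*(tf_animal - tf_mean),
# so group medians follow the full coupling law while within-group dynamic
# elastance scatter matches the printed per-group SDs (which are much
# tighter than the raw TF scatter would imply for the milder grades).
#
# Tissue-fraction targets (tf mean/sd, as fractions) are the printed per-group
# morphometry values the synthetic cohort emulates.
version: 1
tf_ref: 0.225
beta: 3.5
mechanics_common:
  n_compartments: 10
  h_lung_ref: 3.8         # cmH2O/mL, grade-A0 all-open tissue elastance scale
  eta_mean: 0.30          # hysteresivity G/H
  eta_sd: 0.02
  rc_mean: 0.06           # central airway resistance, cmH2O.s/mL
  rc_sd: 0.01
  ic_mean: 0.00025        # central inertance, cmH2O.s^2/mL
  ic_sd: 0.00003
  raw_peep_slope: 0.05    # airway dilation relief per cmH2O PEEP, saturates
  raw_peep_cap: 4.0       #   at this PEEP (R_high plateau)
  h_peep_slope: 0.012     # mild tissue softening per cmH2O PEEP
grades:
  A0_native:
    grade: 0
    tf: {mean: 0.225, sd: 0.015}
    mechanics:
      raw_lung: {mean: 0.05, sd: 0.01}
      het_cv: 0.10
      tf_shrink: 0.40
      pc: {mean: -5.0, sd: 1.0, max: -0.5}
    histology:
      n_cells: 300
      n_vessels: [2, 3]
      vessel_r: [25, 45]
      n_infiltrates: [0, 0]
      infiltrate_r0: [0, 0]
      n_consolidations: [0, 0]
      consolidation_r0: [0, 0]
  A0_iso:
    grade: 0
    tf: {mean: 0.225, sd: 0.015}
    mechanics:
      raw_lung: {mean: 0.05, sd: 0.01}
      het_cv: 0.10
      tf_shrink: 0.40
      pc: {mean: -5.0, sd: 1.0, max: -0.5}
    histology:
      n_cells: 300
      n_vessels: [2, 3]
      vessel_r: [25, 45]
      n_infiltrates: [0, 0]
      infiltrate_r0: [0, 0]
      n_consolidations: [0, 0]
      consolidation_r0: [0, 0]
  A1:
    grade: 1
    tf: {mean: 0.261, sd: 0.042}
    mechanics:
      raw_lung: {mean: 0.05, sd: 0.01}
      het_cv: 0.20
      tf_shrink: 0.25
      pc: {mean: -0.2, sd: 1.2}
    histology:
      n_cells: 300
      n_vessels: [3, 4]
      vessel_r: [25, 45]
      n_infiltrates: [5, 9]
      infiltrate_r0: [8, 16]
      n_consolidations: [0, 0]
      consolidation_r0: [0, 0]
  A2:
    grade: 2
    tf: {mean: 0.338, sd: 0.051}
    mechanics:
      raw_lung: {mean: 0.10, sd: 0.02}
      het_cv: 0.35
      tf_shrink: 0.70
      pc: {mean: 1.0, sd: 2.0}
    histology:
      n_cells: 300
      n_vessels: [3, 5]
      vessel_r: [25, 50]
      n_infiltrates: [14, 20]
      infiltrate_r0: [12, 26]
      n_consolidations: [0, 0]
      consolidation_r0: [0, 0]
  A3:
    grade: 3
    tf: {mean: 0.621, sd: 0.047}
    mechanics:
      raw_lung: {mean: 0.30, sd: 0.05}
      het_cv: 0.50
      tf_shrink: 0.70
      pc: {mean: 2.0, sd: 4.0}
    histology:
      n_cells: 300
      n_vessels: [3, 5]
      vessel_r: [25, 50]
      n_infiltrates: [10, 14]
      infiltrate_r0: [25, 50]
      n_consolidations: [6, 10]
      consolidation_r0: [20, 45]
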