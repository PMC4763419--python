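# Data-generating configuration for the synthetic trauma cohorts.
#
# event_model: the TRUE logistic model for 24-h mortality used by the
# generator -- a 4-knot restricted cubic spline in systolic blood pressure
# plus linear Glasgow coma scale.  Coefficients are fixed package constants
# (risk falls steeply with SBP below ~120 mmHg and flattens above; each GCS
# point lowers the log-odds by 0.28) with the intercept set so that overall
# 24-h mortality is about 6-7 %.
#
# samples: marginal targets (median, q1, q3 / proportions) for the emulated
# study periods.
event_model:
  sbp_knots: [105.0, 115.0, 124.0, 135.0]
  sbp_coefficients: [-0.0608, 0.0437, -0.0447]
  gcs_coefficient: -0.28
  intercept: 6.565
hospital_shares:
  AA: 0.40
  BB: 0.30
  CC: 0.30
samples:
  updating:
    n_total: 1629
    arrival_start: "2013-10-01"
    arrival_end: "2014-01-11"
    age: [35, 24, 47]
    sbp: [116, 106, 125]
    hr: [90, 80, 98]
    delay_h: [7, 2, 28]
    p_male: 0.80
    p_transferred: 0.68
    mechanism_probs:
      fall: 0.27
      railway: 0.07
      road_traffic: 0.46
      assault: 0.09
      burn: 0.06
      other: 0.05
  validation:
    n_total: 2811
    arrival_start: "2014-01-12"
    arrival_end: "2014-07-23"
    age: [35, 25, 46]
    sbp: [120, 110, 130]
    hr: [89, 80, 98]
    delay_h: [7, 2, 26]
    p_male: 0.80
    p_transferred: 0.71
    mechanism_probs:
      fall: 0.26
      railway: 0.06
      road_traffic: 0.46
      assault: 0.11
      burn: 0.07
      other: 0.04
  full:
    n_total: 4440
    arrival_start: "2013-10-01"
    arrival_end: "2014-07-23"
    age: [35, 25, 46]
    sbp: [118, 108, 128]
    hr: [89, 80, 98]
    delay_h: [7, 2, 27]
    p_male: 0.80
    p_transferred: 0.70
    mechanism_probs:
      fall: 0.26
      railway: 0.06
      road_traffic: 0.46
      assault: 0.11
      burn: 0.07
      other: 0.04
# Default per-variable missingness fractions of each period (always-observed
# fields are omitted; they have 0 % missing).
missingness:
  updating: {sbp: 0.20, hr: 0.18, gcs: 0.20, delay_h: 0.06}
  validation: {sbp: 0.09, hr: 0.03, gcs: 0.08, delay_h: 0.04}
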