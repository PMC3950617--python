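name: table2_baseline
description: >
  Baseline patient-flow scenario: hourly arrival rates per CTAS level,
  direct inpatient admissions, triangular ED treatment time (hours) and
  inpatient length of stay (days), with 20 ED beds and 125 IU beds.
arrivals:
  ctas_1: 0.075
  ctas_2: 0.662
  ctas_3: 3.749
  ctas_4: 2.86
  ctas_5: 0.226
  total: 7.572
  direct_iu: 0.267
  iu_from_ed: 0.479
  iu_total: 0.746
ed_service: {lower: 0.1, mode: 0.5, upper: 1.0, unit: hours}
iu_los: {lower: 1, mode: 4, upper: 7, unit: days}
beds:
  ed: 20
  iu: 125
options:
  wait_metric: queueing_delay
  bondi_scaling: scaled
fast_track:
  enabled: false
  fraction: 0.2
  literal_eq14: false
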