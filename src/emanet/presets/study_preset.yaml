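# Default ground-truth model for the synthetic twice-daily EMA study:
# 62 persons x 9 weekdays x {AM, PM}, four nodes on a 0-100 scale.
#
# Temporal matrix rows are afternoon targets, columns are morning sources
# (entry [j, k] = effect of node k at AM on node j at PM); slope_sd holds the
# between-person SDs of those lagged effects.  Partial-correlation matrices
# use the zero-diagonal convention.  Grand means and total SDs follow the
# published descriptives; the total SD is split into a between-person part
# (fraction 0.8) and a within-person innovation part (fraction 0.6), giving
# total variance = (0.8^2 + 0.6^2) = 1.0 times the published variance.
nodes: [self_control, response_inhibition, anger, anger_rumination]
grand_means: [74.61, 56.14, 10.97, 12.59]
total_sds: [21.35, 23.80, 21.95, 23.01]
between_sd_fraction: 0.8
within_sd_fraction: 0.6
temporal:
  - [0.170, 0.174, 0.000, 0.000]
  - [0.000, 0.184, 0.000, 0.000]
  - [0.000, 0.000, -0.006, 0.189]
  - [0.000, 0.000, 0.000, 0.268]
slope_sd:
  - [0.065, 0.141, 0.000, 0.000]
  - [0.000, 0.240, 0.000, 0.000]
  - [0.000, 0.000, 0.089, 0.302]
  - [0.000, 0.000, 0.000, 0.415]
between_partial:
  - [0.000, 0.000, -0.491, 0.000]
  - [0.000, 0.000, -0.150, 0.000]
  - [-0.491, -0.150, 0.000, 0.291]
  - [0.000, 0.000, 0.291, 0.000]
contemporaneous_partial:
  - [0.000, 0.000, -0.138, 0.000]
  - [0.000, 0.000, 0.000, 0.000]
  - [-0.138, 0.000, 0.000, 0.000]
  - [0.000, 0.000, 0.000, 0.000]
compliance:
  self_report: 0.85
  task: 0.793
n_persons: 62
n_days: 9
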