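# Genotype presets for the synthetic cohort generators.
#
# Means are the published cohort means for each genotype; per-embryo spreads
# (sd fields) are back-computed from the published SEM as sd = SEM * sqrt(n),
# since only mean +/- SEM per genotype is reported. Angles in degrees, stage
# durations in hours, growth rates in um^2/min.
#
# division_failure_prob is the per-cytokinesis failure probability of the
# branching division model. For the double mutant it solves
# (2 - p)^5 = 2.9, the mean blastocyst-stage cell count of that genotype,
# so five attempted cleavage waves reproduce the observed count.
#
# compaction_duration_h: time for the contact angle to ramp from angle_start
# to angle_end. Defaults to the 8-cell stage duration (compaction completes
# by the fourth cleavage); mzMyh10 keeps compacting into the 16-cell stage,
# so its ramp is longer than its 8-cell stage.

WT:
  angle_start: 87.0          # 87 +/- 3 (n=23)
  angle_start_sd: 14.39
  angle_end: 147.0           # 147 +/- 2
  angle_end_sd: 9.59
  stage8_duration_h: 7.0     # 7.0 +/- 0.3
  stage8_sd_h: 1.44
  compaction_duration_h: null
  division_failure_prob: 0.0
  reversion_prob: 0.0
  growth_rate_um2_min: 3.9   # 3.9 +/- 0.5 (n=20)
  growth_rate_sd: 2.24
  oscillating_fraction: 0.857   # 18/21
  final_cell_count_mean: 58.1
  lumen_before_fifth_prob: 0.0

mzMyh9:
  angle_start: 85.0          # 85 +/- 2 (n=15)
  angle_start_sd: 7.75
  angle_end: 125.0           # 125 +/- 4
  angle_end_sd: 15.49
  stage8_duration_h: 9.8     # 9.8 +/- 0.5
  stage8_sd_h: 1.94
  compaction_duration_h: null
  division_failure_prob: 0.2    # rough emulation of the reduced cell count
  reversion_prob: 0.05          # reverting cleavages are seen in this genotype
  growth_rate_um2_min: 3.9   # 3.9 +/- 1.0 (n=9)
  growth_rate_sd: 3.0
  oscillating_fraction: 0.067   # 1/15
  final_cell_count_mean: 25.2
  lumen_before_fifth_prob: 0.4545   # 5/11 open a lumen before the fifth wave

mMyh9:
  angle_start: 85.0
  angle_start_sd: 7.75
  angle_end: 125.0
  angle_end_sd: 15.49
  stage8_duration_h: 9.8
  stage8_sd_h: 1.94
  compaction_duration_h: null
  division_failure_prob: 0.2
  reversion_prob: 0.05
  growth_rate_um2_min: 3.9
  growth_rate_sd: 3.0
  oscillating_fraction: 0.0     # 0/8
  final_cell_count_mean: 25.2
  lumen_before_fifth_prob: 0.4545

mzMyh10:
  angle_start: 87.0          # 87 +/- 5 (n=11)
  angle_start_sd: 16.58
  angle_end: 148.0           # 148 +/- 4 by the end of the 16-cell stage
  angle_end_sd: 13.27
  stage8_duration_h: 7.0     # no cell-cycle delay in this genotype
  stage8_sd_h: 1.44
  compaction_duration_h: 14.0   # slow ramp: ~121 deg before the 4th cleavage
  division_failure_prob: 0.0
  reversion_prob: 0.0
  growth_rate_um2_min: 4.0   # 4.0 +/- 0.5 (n=7)
  growth_rate_sd: 1.32
  oscillating_fraction: 0.273   # 3/11
  final_cell_count_mean: 58.0
  lumen_before_fifth_prob: 0.0

mMyh10:
  angle_start: 87.0
  angle_start_sd: 16.58
  angle_end: 148.0
  angle_end_sd: 13.27
  stage8_duration_h: 7.0
  stage8_sd_h: 1.44
  compaction_duration_h: 14.0
  division_failure_prob: 0.0
  reversion_prob: 0.0
  growth_rate_um2_min: 4.0
  growth_rate_sd: 1.32
  oscillating_fraction: 0.4     # 8/20
  final_cell_count_mean: 58.0
  lumen_before_fifth_prob: 0.0

mzMyh9;mzMyh10:
  angle_start: 85.0
  angle_start_sd: 7.75
  angle_end: 117.0           # plateau 117 +/- 4 (n=3)
  angle_end_sd: 6.93
  stage8_duration_h: 12.0    # cell-cycle delay more severe than mzMyh9
  stage8_sd_h: 3.0
  compaction_duration_h: null
  division_failure_prob: 0.76269   # (2 - p)^5 = 2.9 cells
  reversion_prob: 0.0
  growth_rate_um2_min: 5.8   # 5.8 +/- 1.5 (n=5)
  growth_rate_sd: 3.35
  oscillating_fraction: 0.0     # 0/8
  final_cell_count_mean: 2.9
  lumen_before_fifth_prob: 0.0
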