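coefficients:
- 4.12
- 0.059665871121718374
- 0.0
- 0.10718419961985336
correlation:
- - 1.0
  - -0.202
  - 0.404
  - 0.268
  - 0.079
  - -0.25
  - -0.315
  - 0.24
- - -0.202
  - 1.0
  - -0.075
  - 0.061
  - -0.04
  - 0.47
  - 0.298
  - -0.062
- - 0.404
  - -0.075
  - 1.0
  - 0.51
  - 0.039
  - -0.147
  - -0.223
  - 0.116
- - 0.268
  - 0.061
  - 0.51
  - 1.0
  - 0.0
  - -0.089
  - -0.179
  - 0.12
- - 0.079
  - -0.04
  - 0.039
  - 0.0
  - 1.0
  - -0.045
  - -0.04
  - 0.034
- - -0.25
  - 0.47
  - -0.147
  - -0.089
  - -0.045
  - 1.0
  - 0.658
  - -0.034
- - -0.315
  - 0.298
  - -0.223
  - -0.179
  - -0.04
  - 0.658
  - 1.0
  - -0.163
- - 0.24
  - -0.062
  - 0.116
  - 0.12
  - 0.034
  - -0.034
  - -0.163
  - 1.0
department_probs:
- 0.1525
- 0.0762
- 0.3255
- 0.0792
- 0.088
- 0.1202
- 0.1584
env_polarity: 1
hcc_logmean: 0.5185139398778874
hcc_logsd: 0.334
missing_rate: 0.0
n: 341
noise_sd: 1.0
pattern: differential_susceptibility
pattern_env: job_control
pattern_outcome: pe
scale_means:
  coworker_support: 12.51
  dp: 2.45
  ee: 3.42
  job_control: 62.38
  pe: 4.12
  psych_demands: 33.69
  supervisor_support: 11.84
scale_sds:
  coworker_support: 1.5
  dp: 1.33
  ee: 1.51
  job_control: 8.38
  pe: 1.24
  psych_demands: 6.93
  supervisor_support: 1.84
seed: 0
shift_probs:
- 0.9003
- 0.0997
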