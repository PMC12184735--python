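# Packaged demo configuration: small simulated ward, phase-3 policy.
seed: 7
log_level: INFO
phase_name: P3
simulator:
  n_patients: 12
  artifact_rate: 0.05
  mix:
    epidural: 0.5
    deterioration: 0.1
audit:
  timezone: UTC
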