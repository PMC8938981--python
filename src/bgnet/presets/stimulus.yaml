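amplitude: 5000.0
fraction: 0.5
pulse_dur: 4.0
ramp_ms: 3.5
supp_depth: 0.15
supp_dur: 20.0
targets:
- D1-SPN
- D2-SPN
- FSI
- STN
weights:
  D1-SPN: 0.65
  D2-SPN: 2.8
  FSI: 1.0
  STN: 1.5
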