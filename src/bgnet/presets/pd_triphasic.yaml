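n_sources: {}
rates:
  D1-SPN: 3907.6
  D2-SPN: 3373.8
  FSI: 2000.0
  GPe-TA: 37.2
  GPe-TI: 1.0
  SNr: 50.0
  STN: 606.4
weights:
  D1-SPN: 2.0
  D2-SPN: 2.0
  FSI: 4.0
  GPe-TA: 8.0
  GPe-TI: 4.0
  SNr: 4.0
  STN: 4.0
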