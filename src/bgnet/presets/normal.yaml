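n_sources: {}
rates:
  D1-SPN: 3000.0
  D2-SPN: 3000.0
  FSI: 1600.0
  GPe-TA: 16.2
  GPe-TI: 1.2
  SNr: 1189.0
  STN: 466.0
weights:
  D1-SPN: 2.0
  D2-SPN: 2.0
  FSI: 4.0
  GPe-TA: 8.0
  GPe-TI: 4.0
  SNr: 4.0
  STN: 4.0
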