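schema_version: 1
states:
- G16
- C17_pause
- C17_slow
- G18plus
transitions:
- from: G16
  to: C17_pause
  k: 10.0
- from: C17_pause
  to: G18plus
  k: 0.1715
- from: C17_pause
  to: C17_slow
  k: 0.028499999999999998
- from: C17_slow
  to: G18plus
  k: 0.01
init:
  G16: 1.0
substrates: {}
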