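schema_version: 1
states:
- G16
- C17_pause
- C17_slow
- C17_bypass
- G18plus
transitions:
- from: G16
  to: C17_pause
  k: 8.0
- from: G16
  to: C17_bypass
  k: 1.9999999999999996
- from: C17_bypass
  to: G18plus
  k: 12.0
- from: C17_pause
  to: G18plus
  k: 0.16437500000000002
- from: C17_pause
  to: C17_slow
  k: 0.035625
- from: C17_slow
  to: G18plus
  k: 0.01
init:
  G16: 1.0
substrates: {}
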