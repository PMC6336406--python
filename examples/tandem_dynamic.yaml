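schema_version: 1
states:
- A0
- P1
- S1
- T
- P2
- S2
- END
transitions:
- from: A0
  to: P1
  k: 8.5
- from: A0
  to: S1
  k: 1.5
- from: P1
  to: T
  k: 0.2
- from: S1
  to: T
  k: 0.01
- from: T
  to: P2
  k: 8.5
- from: T
  to: S2
  k: 1.5
- from: P2
  to: END
  k: 0.2
- from: S2
  to: END
  k: 0.01
init:
  A0: 1.0
substrates: {}
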