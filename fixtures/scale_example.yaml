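name: stroke4_custom
levels:
- none
- minor stroke
- major stroke
- fatal stroke
mapping:
  minor: 1
  major: 2
nonfatal_default: 1
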