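SA:
- label: U-13C3
  pattern: '111'
  purity: 99.0
  price: 120.0
- label: 1-13C1
  pattern: '100'
  purity: 99.0
  price: 45.0
- label: 12C
  pattern: '000'
  purity: 99.0
  price: 0.4
SB:
- label: U-13C2
  pattern: '11'
  purity: 99.0
  price: 210.0
- label: 1-13C1
  pattern: '10'
  purity: 99.0
  price: 80.0
- label: 12C
  pattern: '00'
  purity: 99.0
  price: 0.6
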