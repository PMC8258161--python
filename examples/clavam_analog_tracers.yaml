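GLX:
- label: U-13C3
  pattern: '111'
  purity: 99.0
  price: 110.0
- label: 1,3-13C2
  pattern: '101'
  purity: 99.0
  price: 165.0
- label: 2-13C1
  pattern: '010'
  purity: 99.0
  price: 99.0
- label: 12C
  pattern: '000'
  purity: 99.0
  price: 0.36
AGX:
- label: U-13C5
  pattern: '11111'
  purity: 99.0
  price: 3449.0
- label: 5-13C1
  pattern: '00001'
  purity: 99.0
  price: 1150.0
- label: 12C
  pattern: '00000'
  purity: 99.0
  price: 0.9
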