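radical_toy
  molfig

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 N  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    1.7321   -0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    2.5981    0.5000    0.0000 O  0  0  0  0  0  0  0  0  0  0  0  0
    1.7321   -1.0000    0.0000 O  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  1  0  0  0  0
  3  4  2  0  0  0  0
  3  5  1  0  0  0  0
M  CHG  2   1   1   5  -1
M  RAD  1   2   2
M  END
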