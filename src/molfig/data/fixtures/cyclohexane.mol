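cyclohexane
  molfig

  6  6  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    1.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    2.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    1.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    0.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  1  0  0  0  0
  3  4  1  0  0  0  0
  4  5  1  0  0  0  0
  5  6  1  0  0  0  0
  1  6  1  0  0  0  0
M  END
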