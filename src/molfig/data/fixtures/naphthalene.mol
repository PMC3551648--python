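naphthalene
  molfig

 10 11  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    1.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    2.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -0.9962    1.9128    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -0.4067    1.9135    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -1.2728    1.4135    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -0.2880    1.5872    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    1.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    0.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0  0  0  0
  2  3  1  0  0  0  0
  3  4  2  0  0  0  0
  4  5  1  0  0  0  0
  5  6  2  0  0  0  0
  6  7  1  0  0  0  0
  7  8  2  0  0  0  0
  8  9  1  0  0  0  0
  4  9  1  0  0  0  0
  9 10  2  0  0  0  0
  1 10  1  0  0  0  0
M  END
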