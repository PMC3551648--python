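norepinephrine
  molfig

 12 12  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 N  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    1.7321   -0.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    2.5981    0.5000    0.0000 O  0  0  0  0  0  0  0  0  0  0  0  0
    1.7321   -1.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660   -1.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    0.8660   -2.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    1.7321   -3.0000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    1.7321   -4.0000    0.0000 O  0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -2.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
    3.4641   -3.0000    0.0000 O  0  0  0  0  0  0  0  0  0  0  0  0
    2.5981   -1.5000    0.0000 C  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  1  0  0  0  0
  3  4  1  1  0  0  0
  3  5  1  0  0  0  0
  5  6  2  0  0  0  0
  6  7  1  0  0  0  0
  7  8  2  0  0  0  0
  8  9  1  0  0  0  0
  8 10  1  0  0  0  0
 10 11  1  0  0  0  0
 10 12  2  0  0  0  0
  5 12  1  0  0  0  0
M  END
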