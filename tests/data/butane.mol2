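@<TRIPOS>MOLECULE
butane
 14 13 0 0 0
SMALL
GASTEIGER

@<TRIPOS>ATOM
      1 C           0.0000    0.0000    0.0000 C.3     1  UNL1       -0.0653
      2 C           1.5260    0.0000    0.0000 C.3     1  UNL1       -0.0562
      3 C           2.0729    1.4246    0.0000 C.3     1  UNL1       -0.0562
      4 C           3.5989    1.4246    0.0000 C.3     1  UNL1       -0.0653
      5 H          -0.3633    0.5138   -0.8900 H       1  UNL1        0.0230
      6 H          -0.3633   -1.0277   -0.0000 H       1  UNL1        0.0230
      7 H          -0.3633    0.5138    0.8900 H       1  UNL1        0.0230
      8 H           1.8755   -0.5233    0.8900 H       1  UNL1        0.0263
      9 H           1.8755   -0.5233   -0.8900 H       1  UNL1        0.0263
     10 H           1.7234    1.9480    0.8900 H       1  UNL1        0.0263
     11 H           1.7234    1.9480   -0.8900 H       1  UNL1        0.0263
     12 H           3.9622    0.9108   -0.8900 H       1  UNL1        0.0230
     13 H           3.9622    2.4523    0.0000 H       1  UNL1        0.0230
     14 H           3.9622    0.9108    0.8900 H       1  UNL1        0.0230
@<TRIPOS>BOND
     1     1     2    1
     2     2     3    1
     3     3     4    1
     4     1     5    1
     5     1     6    1
     6     1     7    1
     7     2     8    1
     8     2     9    1
     9     3    10    1
    10     3    11    1
    11     4    12    1
    12     4    13    1
    13     4    14    1
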