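"""Embedded SDF (V2000) fixture geometries.

Synthetic idealized structures built from exact internal
coordinates (regular hexagonal rings, exact tetrahedral and
three-fold-symmetric groups); generated once and frozen.
"""

MOLBLOCKS = {
    'butane': '''butane
     RDKit          3D

 14 13  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5260    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0729    1.4246    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5989    1.4246    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3633    0.5138   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3633   -1.0277   -0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3633    0.5138    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.8755   -0.5233    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.8755   -0.5233   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.7234    1.9480    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.7234    1.9480   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9622    0.9108   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9622    2.4523    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9622    0.9108    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  1  5  1  0
  1  6  1  0
  1  7  1  0
  2  8  1  0
  2  9  1  0
  3 10  1  0
  3 11  1  0
  4 12  1  0
  4 13  1  0
  4 14  1  0
M  END
''',
    'ethylbenzene': '''ethylbenzene
     RDKit          3D

 18 18  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4700    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.9000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.4469    0.0000    1.4246 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.2633   -0.8900   -0.5138 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.2633    0.8900   -0.5138 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0974   -0.8900    1.9480 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.5365   -0.0000    1.3956 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0974    0.8900    1.9480 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  2  7  1  0
  3  8  1  0
  4  9  1  0
  5 10  1  0
  6 11  1  0
  1 12  1  0
 12 13  1  0
 12 14  1  0
 12 15  1  0
 13 16  1  0
 13 17  1  0
 13 18  1  0
M  END
''',
    'tert-butylbenzene': '''tert-butylbenzene
     RDKit          3D

 24 24  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4700    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.9000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.4100    0.7212    1.2492 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0467    0.2074    2.1392 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000    0.7212    1.2492 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0467    1.7489    1.2492 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.4100   -1.4425    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0467   -1.9563   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000   -1.4425    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0467   -1.9563    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.4100    0.7212   -1.2492 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0467    1.7489   -1.2492 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.5000    0.7212   -1.2492 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0467    0.2074   -2.1392 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  2  7  1  0
  3  8  1  0
  4  9  1  0
  5 10  1  0
  6 11  1  0
  1 12  1  0
 12 13  1  0
 13 14  1  0
 13 15  1  0
 13 16  1  0
 12 17  1  0
 17 18  1  0
 17 19  1  0
 17 20  1  0
 12 21  1  0
 21 22  1  0
 21 23  1  0
 21 24  1  0
M  END
''',
    'biphenyl': '''biphenyl
     RDKit          3D

 22 23  0  0  0  0  0  0  0  0999 V2000
   -0.7400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4350    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8250    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5200    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8250   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4350   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8950    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3650    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.6000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3650   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8950   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.5200    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.8250    1.0425    0.6019 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4350    1.0425    0.6019 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4350   -1.0425   -0.6019 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.8250   -1.0425   -0.6019 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.6000   -0.0000   -0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.3650    1.8525    1.0695 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.8950    1.8525    1.0695 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.8950   -1.8525   -1.0695 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.3650   -1.8525   -1.0695 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  2  7  1  0
  3  8  1  0
  4  9  1  0
  5 10  1  0
  6 11  1  0
 12 13  2  0
 13 14  1  0
 14 15  2  0
 15 16  1  0
 16 17  2  0
 17 12  1  0
 12 18  1  0
 13 19  1  0
 14 20  1  0
 16 21  1  0
 17 22  1  0
  1 15  1  0
M  END
''',
    'para-difluorobenzene': '''para-difluorobenzene
     RDKit          3D

 12 12  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.7400    0.0000    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7400    0.0000    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  2  7  1  0
  3  8  1  0
  5  9  1  0
  6 10  1  0
  1 11  1  0
  4 12  1  0
M  END
''',
    'fluoro-ethylbenzene': '''fluoro-ethylbenzene
     RDKit          3D

 18 18  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.9000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.4469    0.0000    1.4246 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.2633   -0.8900   -0.5138 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.2633    0.8900   -0.5138 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0974   -0.8900    1.9480 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.5365   -0.0000    1.3956 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.0974    0.8900    1.9480 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7400    0.0000    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  2  7  1  0
  3  8  1  0
  5  9  1  0
  6 10  1  0
  1 11  1  0
 11 12  1  0
 11 13  1  0
 11 14  1  0
 12 15  1  0
 12 16  1  0
 12 17  1  0
  4 18  1  0
M  END
''',
    'sulfone-analogue': '''sulfone-analogue
     RDKit          3D

 21 21  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2038    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350    2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4700    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2350   -2.1391    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.1600    0.0000    0.0000 S   0  0  0  0  0  0  0  0  0  0  0  0
    3.5810    0.6885    1.1926 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.5810    0.6885   -1.1926 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.5955   -1.7465    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.1106   -1.9595    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.1848   -2.2234   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.1848   -2.2234    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.5419   -1.5012    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.3273   -3.0277    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.5419   -1.5012   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
  2  7  1  0
  3  8  1  0
  4  9  1  0
  5 10  1  0
  6 11  1  0
  1 12  1  0
 12 13  2  0
 12 14  2  0
 12 15  1  0
 15 16  1  0
 15 17  1  0
 15 18  1  0
 16 19  1  0
 16 20  1  0
 16 21  1  0
M  END
''',
}
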