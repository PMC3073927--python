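# Default torsion library: one rule per line, "SMARTS angle angle ...".
# The SMARTS must describe exactly four connected atoms; the middle two
# atoms identify the rotatable bond.  The first matching rule (file
# order) wins; bonds no rule matches fall back to a 12-point grid at
# 30-degree spacing.  Angles are degrees in [0, 360).
#
# These defaults are this package's own and are deliberately coarse;
# replace the file (--torlib) for finer, bond-specific angle sets.

# amide C-N: planar, cis/trans only
[OX1]=[CX3]-[NX3]~[!#1]    0 180
# ester / acid C-O: planar
[OX1]=[CX3]-[OX2]~[!#1]    0 180
# conjugated carbonyl C-C: planar-dominant
[OX1]=[CX3]-[CX3,c]~[!#1]  0 90 180 270
# sp3 carbon - sp3 carbon
[!#1]~[CX4]-[CX4]~[!#1]    0 30 60 90 120 150 180 210 240 270 300 330
# aryl / sp2 carbon - sp3 carbon
[!#1]~[c,CX3]-[CX4]~[!#1]  0 30 60 90 120 150 180 210 240 270 300 330
# biaryl and conjugated sp2 - sp2
[!#1]~[c,CX3]-[c,CX3]~[!#1]  0 30 60 90 120 150 180 210 240 270 300 330
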