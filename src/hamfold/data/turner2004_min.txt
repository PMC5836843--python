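# hamfold nearest-neighbor parameter table
# Turner-2004-style free energies, dG at 37 C (310.15 K), kcal/mol.
# No dangling ends, no coaxial stacking, no tetraloop bonuses: the model is a
# minimal nearest-neighbor set (stacking + loop-length penalties + affine
# multiloop) kept deliberately small so the partition-function recursions and
# the enumeration oracle share an exactly identical loop decomposition.
#
# Sections:
#   [pairs]      pair-type order used by all per-pair tables
#   [stack]      6x6 dG37 for pair (i,j) stacked on pair (i+1,j-1)
#   [hairpin]    loop-size initiation dG37 (size = unpaired bases); sizes
#                beyond the last entry are extrapolated as
#                dG(n) = dG(nmax) + 1.75 R T ln(n / nmax)
#   [bulge]      bulge-loop initiation dG37 by total unpaired bases
#   [interior]   internal-loop initiation dG37 by total unpaired bases
#   [asymmetry]  per-nucleotide internal-loop asymmetry penalty and its cap
#   [multiloop]  affine multiloop: a (closing) + b per branch + c per unpaired
#   [terminal]   penalty per non-GC closing pair of hairpin/bulge/internal loops
#   [enthalpy_ratio]  dH/dG37 assumed for stacks when rescaling to T != 37 C
#                     (loop initiations are treated as purely entropic)

name turner2004-min
version 1.0

[pairs]
AU CG GC UA GU UG

[stack]
-0.93 -2.24 -2.08 -1.10 -0.55 -1.36
-2.11 -3.26 -2.36 -2.08 -1.41 -2.11
-2.35 -3.42 -3.26 -2.24 -1.53 -2.51
-1.33 -2.35 -2.11 -0.93 -1.27 -1.00
-1.00 -2.51 -2.11 -1.36  0.47  1.29
-1.27 -1.53 -1.41 -0.55 -0.57  0.47

[hairpin]
3 5.4
4 5.6
5 5.7
6 5.4
7 6.0
8 5.5
9 6.4
10 6.5

[bulge]
1 3.8
2 2.8
3 3.2
4 3.6
5 4.0
6 4.4

[interior]
2 1.5
3 1.6
4 1.7
5 2.0
6 2.0

[asymmetry]
0.6 3.0

[multiloop]
3.4 0.4 0.0

[terminal]
0.5

[enthalpy_ratio]
5.0
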