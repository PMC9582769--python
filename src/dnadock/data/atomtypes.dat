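# Atom-type parameters.
# Columns: atomtype vdw_rstar(A) vdw_eps(kcal/mol) asp(kcal/(mol*A^2))
# vdW r*/eps are the AMBER94 6-12 values (r* is the energy-minimum half-distance;
# pair minimum at Rij = ri* + rj*).
# asp is the atomic solvation coefficient multiplying *buried* accessible area in
# the desolvation term (negative = burial favourable). Values are an
# Eisenberg/McLachlan-style transfer set with the sign convention of this package;
# the whole column is user-editable to swap solvation models.
# Nucleotide-only atom types carry '-' here: their asp is resolved through the
# nucleotide->protein type map (nucmap.dat).
C   1.9080 0.0860 -0.016
CA  1.9080 0.0860 -0.016
CB  1.9080 0.0860 -0.016
CC  1.9080 0.0860 -0.016
CN  1.9080 0.0860 -0.016
CR  1.9080 0.0860 -0.016
CV  1.9080 0.0860 -0.016
CW  1.9080 0.0860 -0.016
C*  1.9080 0.0860 -0.016
CT  1.9080 0.1094 -0.016
CK  1.9080 0.0860 -
CM  1.9080 0.0860 -
CQ  1.9080 0.0860 -
N   1.8240 0.1700 0.006
NA  1.8240 0.1700 0.006
NB  1.8240 0.1700 0.006
N2  1.8240 0.1700 0.050
N3  1.8240 0.1700 0.050
N*  1.8240 0.1700 -
NC  1.8240 0.1700 -
O   1.6612 0.2100 0.006
O2  1.6612 0.2100 0.024
OH  1.7210 0.2104 0.006
OS  1.6837 0.1700 -
S   2.0000 0.2500 -0.021
SH  2.0000 0.2500 -0.021
P   2.1000 0.2000 -
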