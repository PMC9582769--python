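# Nucleotide atom-type map: each atom type that occurs only in the
# deoxyribonucleotide templates is mapped to the chemically nearest protein
# atom type for atomic-solvation-parameter lookup (the vdW parameters of the
# nucleotide types themselves are taken from atomtypes.dat).
# Columns: nucleotide_type protein_type
N*  N
NC  NB
CK  CA
CQ  CA
CM  CA
OS  OH
P   S
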