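# AMBER94 (Cornell et al.) all-atom residue templates, deoxyribonucleotides.
# Columns: resname atom element parent charge atomtype
# Internal-residue templates (5'-phosphate included; the 5'-terminal residue of a
# chain simply lacks P/OP1/OP2 and those template rows are unused there).
# Atom names follow PDB v3 (primes); the reader canonicalises * -> ' and O1P -> OP1.
DA P    P -    1.1659 P
DA OP1  O -   -0.7761 O2
DA OP2  O -   -0.7761 O2
DA O5'  O -   -0.4954 OS
DA C5'  C -   -0.0069 CT
DA H5'  H C5'  0.0754 -
DA H5'' H C5'  0.0754 -
DA C4'  C -    0.1629 CT
DA H4'  H C4'  0.1176 -
DA O4'  O -   -0.3691 OS
DA C1'  C -    0.0431 CT
DA H1'  H C1'  0.1838 -
DA N9   N -   -0.0268 N*
DA C8   C -    0.1607 CK
DA H8   H C8   0.1877 -
DA N7   N -   -0.6175 NB
DA C5   C -    0.0725 CB
DA C6   C -    0.6897 CA
DA N6   N -   -0.9123 N2
DA H61  H N6   0.4167 -
DA H62  H N6   0.4167 -
DA N1   N -   -0.7624 NC
DA C2   C -    0.5716 CQ
DA H2   H C2   0.0598 -
DA N3   N -   -0.7417 NC
DA C4   C -    0.3800 CB
DA C3'  C -    0.0713 CT
DA H3'  H C3'  0.0985 -
DA C2'  C -   -0.0854 CT
DA H2'  H C2'  0.0718 -
DA H2'' H C2'  0.0718 -
DA O3'  O -   -0.5232 OS
DG P    P -    1.1659 P
DG OP1  O -   -0.7761 O2
DG OP2  O -   -0.7761 O2
DG O5'  O -   -0.4954 OS
DG C5'  C -   -0.0069 CT
DG H5'  H C5'  0.0754 -
DG H5'' H C5'  0.0754 -
DG C4'  C -    0.1629 CT
DG H4'  H C4'  0.1176 -
DG O4'  O -   -0.3691 OS
DG C1'  C -    0.0358 CT
DG H1'  H C1'  0.1746 -
DG N9   N -    0.0577 N*
DG C8   C -    0.0736 CK
DG H8   H C8   0.1997 -
DG N7   N -   -0.5725 NB
DG C5   C -    0.1991 CB
DG C6   C -    0.4918 C
DG O6   O -   -0.5699 O
DG N1   N -   -0.5053 NA
DG H1   H N1   0.3520 -
DG C2   C -    0.7432 CA
DG N2   N -   -0.9230 N2
DG H21  H N2   0.4235 -
DG H22  H N2   0.4235 -
DG N3   N -   -0.6636 NC
DG C4   C -    0.1814 CB
DG C3'  C -    0.0713 CT
DG H3'  H C3'  0.0985 -
DG C2'  C -   -0.0854 CT
DG H2'  H C2'  0.0718 -
DG H2'' H C2'  0.0718 -
DG O3'  O -   -0.5232 OS
DT P    P -    1.1659 P
DT OP1  O -   -0.7761 O2
DT OP2  O -   -0.7761 O2
DT O5'  O -   -0.4954 OS
DT C5'  C -   -0.0069 CT
DT H5'  H C5'  0.0754 -
DT H5'' H C5'  0.0754 -
DT C4'  C -    0.1629 CT
DT H4'  H C4'  0.1176 -
DT O4'  O -   -0.3691 OS
DT C1'  C -    0.0680 CT
DT H1'  H C1'  0.1804 -
DT N1   N -   -0.0239 N*
DT C6   C -   -0.2209 CM
DT H6   H C6   0.2607 -
DT C5   C -    0.0025 CM
DT C7   C -   -0.2269 CT
DT H71  H C7   0.0770 -
DT H72  H C7   0.0770 -
DT H73  H C7   0.0770 -
DT C4   C -    0.5194 C
DT O4   O -   -0.5563 O
DT N3   N -   -0.4340 NA
DT H3   H N3   0.3420 -
DT C2   C -    0.5677 C
DT O2   O -   -0.5881 O
DT C3'  C -    0.0713 CT
DT H3'  H C3'  0.0985 -
DT C2'  C -   -0.0854 CT
DT H2'  H C2'  0.0718 -
DT H2'' H C2'  0.0718 -
DT O3'  O -   -0.5232 OS
DC P    P -    1.1659 P
DC OP1  O -   -0.7761 O2
DC OP2  O -   -0.7761 O2
DC O5'  O -   -0.4954 OS
DC C5'  C -   -0.0069 CT
DC H5'  H C5'  0.0754 -
DC H5'' H C5'  0.0754 -
DC C4'  C -    0.1629 CT
DC H4'  H C4'  0.1176 -
DC O4'  O -   -0.3691 OS
DC C1'  C -   -0.0116 CT
DC H1'  H C1'  0.1963 -
DC N1   N -   -0.0339 N*
DC C6   C -   -0.0183 CM
DC H6   H C6   0.2293 -
DC C5   C -   -0.5222 CM
DC H5   H C5   0.1863 -
DC C4   C -    0.8439 CA
DC N4   N -   -0.9773 N2
DC H41  H N4   0.4314 -
DC H42  H N4   0.4314 -
DC N3   N -   -0.7748 NC
DC C2   C -    0.7959 C
DC O2   O -   -0.6548 O
DC C3'  C -    0.0713 CT
DC H3'  H C3'  0.0985 -
DC C2'  C -   -0.0854 CT
DC H2'  H C2'  0.0718 -
DC H2'' H C2'  0.0718 -
DC O3'  O -   -0.5232 OS
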