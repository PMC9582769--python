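# Idealized B-DNA nucleotide templates in the Watson-Crick pair frame.
# Strand 1 placement; strand 2 = 180 deg rotation about x of the
# complementary base template. Helix axis z, pair plane z=0,
# C1'-C1' 10.4 A, lambda 54.5 deg, chi (anti) -105 deg.
# Base geometry: CCD ideal coordinates. Replace this file to use
# exact fiber-diffraction coordinates (e.g. 3DNA fiber output).
# Columns: base atom element x y z
A P    P    -4.7670   -6.9594   -5.1199
A OP1  O    -4.1739   -5.7634   -5.7583
A OP2  O    -6.3712   -6.8873   -5.2301
A O5'  O    -4.3365   -7.0094   -3.5699
A C5'  C    -4.8313   -5.8142   -2.9647
A C4'  C    -4.4542   -5.7984   -1.4822
A O4'  O    -3.0202   -5.7091   -1.3186
A C3'  C    -4.9796   -4.5110   -0.7987
A O3'  O    -6.3275   -4.6808   -0.3561
A C2'  C    -4.0180   -4.3679    0.4045
A C1'  C    -2.7838   -5.1974    0.0023
A N9   N    -1.5907   -4.3464    0.0000
A C8   C    -0.2972   -4.7724    0.0000
A N7   N     0.5075   -3.7498   -0.0010
A C5   C    -0.2170   -2.6051   -0.0074
A C6   C     0.0973   -1.2361   -0.0023
A N6   N     1.4147   -0.8121   -0.0029
A N1   N    -0.8997   -0.3571   -0.0024
A C2   C    -2.1583   -0.7524   -0.0010
A N3   N    -2.5008   -2.0230   -0.0001
A C4   C    -1.5728   -2.9749   -0.0000
C P    P    -4.7670   -6.9594   -5.1199
C OP1  O    -4.1739   -5.7634   -5.7583
C OP2  O    -6.3712   -6.8873   -5.2301
C O5'  O    -4.3365   -7.0094   -3.5699
C C5'  C    -4.8313   -5.8142   -2.9647
C C4'  C    -4.4542   -5.7984   -1.4822
C O4'  O    -3.0202   -5.7091   -1.3186
C C3'  C    -4.9796   -4.5110   -0.7987
C O3'  O    -6.3275   -4.6808   -0.3561
C C2'  C    -4.0180   -4.3679    0.4045
C C1'  C    -2.7838   -5.1974    0.0023
C N1   N    -1.5907   -4.3464    0.0000
C C2   C    -1.7237   -3.0086   -0.0000
C O2   O    -2.8402   -2.5164   -0.0004
C N3   N    -0.6564   -2.2116   -0.0006
C C4   C     0.5684   -2.7194   -0.0011
C N4   N     1.6636   -1.8869   -0.0023
C C5   C     0.7414   -4.1184   -0.0052
C C6   C    -0.3527   -4.9150   -0.0000
G P    P    -4.7670   -6.9594   -5.1199
G OP1  O    -4.1739   -5.7634   -5.7583
G OP2  O    -6.3712   -6.8873   -5.2301
G O5'  O    -4.3365   -7.0094   -3.5699
G C5'  C    -4.8313   -5.8142   -2.9647
G C4'  C    -4.4542   -5.7984   -1.4822
G O4'  O    -3.0202   -5.7091   -1.3186
G C3'  C    -4.9796   -4.5110   -0.7987
G O3'  O    -6.3275   -4.6808   -0.3561
G C2'  C    -4.0180   -4.3679    0.4045
G C1'  C    -2.7838   -5.1974    0.0023
G N9   N    -1.5907   -4.3464    0.0000
G C8   C    -0.2955   -4.7739   -0.0000
G N7   N     0.5078   -3.7498    0.0012
G C5   C    -0.2221   -2.6077    0.0020
G C6   C     0.1026   -1.2309    0.0033
G O6   O     1.2648   -0.8637    0.0041
G N1   N    -0.9075   -0.3342   -0.0036
G C2   C    -2.2027   -0.7557    0.0016
G N2   N    -3.2075    0.1782    0.0024
G N3   N    -2.5173   -2.0316    0.0017
G C4   C    -1.5721   -2.9784   -0.0000
T P    P    -4.7670   -6.9594   -5.1199
T OP1  O    -4.1739   -5.7634   -5.7583
T OP2  O    -6.3712   -6.8873   -5.2301
T O5'  O    -4.3365   -7.0094   -3.5699
T C5'  C    -4.8313   -5.8142   -2.9647
T C4'  C    -4.4542   -5.7984   -1.4822
T O4'  O    -3.0202   -5.7091   -1.3186
T C3'  C    -4.9796   -4.5110   -0.7987
T O3'  O    -6.3275   -4.6808   -0.3561
T C2'  C    -4.0180   -4.3679    0.4045
T C1'  C    -2.7838   -5.1974    0.0023
T N1   N    -1.5907   -4.3464    0.0000
T C2   C    -1.6955   -2.9390    0.0000
T O2   O    -2.7675   -2.3310    0.0002
T N3   N    -0.4759   -2.2542    0.0002
T C4   C     0.7938   -2.8118    0.0011
T O4   O     1.8271   -2.1486    0.0025
T C5   C     0.8232   -4.2987    0.0001
T C7   C     2.1558   -4.9761   -0.0001
T C6   C    -0.3432   -4.9573   -0.0000
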