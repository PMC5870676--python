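# Single-bond covalent radii, Angstrom, by element symbol.
# Pinned published compilation (Cordero et al. 2008 consensus values;
# low-spin values for Mn/Fe/Co). Override per scan with a file of the
# same two-column format.
H  0.31
D  0.31
B  0.84
C  0.76
N  0.71
O  0.66
F  0.57
NA 1.66
MG 1.41
AL 1.21
SI 1.11
P  1.07
S  1.05
CL 1.02
K  2.03
CA 1.76
V  1.53
CR 1.39
MN 1.39
FE 1.32
CO 1.26
NI 1.24
CU 1.32
ZN 1.22
AS 1.19
SE 1.20
BR 1.20
MO 1.54
CD 1.44
I  1.39
W  1.62
PT 1.36
AU 1.36
HG 1.32
PB 1.46
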