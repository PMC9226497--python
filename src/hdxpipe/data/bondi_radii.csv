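# Van der Waals radii (Angstrom), Bondi (1964, J Phys Chem 68:441-451),
# with common biomolecular extensions for elements Bondi did not tabulate.
element,radius_A
H,1.20
D,1.20
C,1.70
N,1.55
O,1.52
F,1.47
P,1.80
S,1.80
CL,1.75
BR,1.85
I,1.98
SE,1.90
NA,2.27
MG,1.73
K,2.75
CA,2.31
MN,1.97
FE,1.94
ZN,1.39
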