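# Biological hydrophobicity scale: apparent free energy of membrane
# insertion (dG_app, kcal/mol) measured with the Sec61 translocon.
# Hessa T. et al. (2005) Nature 433:377-381, Table 1.
# Lower (more negative) values = more hydrophobic side chain.
amino_acid	value
A	0.11
C	-0.13
D	3.49
E	2.68
F	-0.32
G	0.74
H	2.06
I	-0.60
K	2.71
L	-0.55
M	-0.10
N	2.05
P	2.23
Q	2.36
R	2.58
S	0.84
T	0.52
V	-0.31
W	0.30
Y	0.68
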