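# Side-chain water-to-bilayer transfer free energies (kcal/mol, relative
# to alanine) from equilibrium folding of OmpLA variants into lipid
# bilayers.  Moon C.P. & Fleming K.G. (2011) PNAS 108:10174-10177.
# Lower (more negative) values = more hydrophobic side chain.  Values may
# be overridden with a custom scale file.
amino_acid	value
A	0.00
C	-0.49
D	3.64
E	3.63
F	-2.20
G	1.15
H	2.33
I	-1.56
K	2.80
L	-1.81
M	-0.76
N	1.33
P	1.40
Q	1.27
R	3.71
S	0.93
T	0.63
V	-0.78
W	-0.95
Y	-0.35
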