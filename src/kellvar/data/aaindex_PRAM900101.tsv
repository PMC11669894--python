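# PRAM900101 hydrophobicity (transfer free energy, kJ/mol; lower = more hydrophobic)
residue	value
A	-6.7
R	51.5
N	20.1
D	38.5
C	-8.4
Q	17.2
E	34.3
G	-4.2
H	12.6
I	-13.0
L	-11.7
K	36.8
M	-14.2
F	-15.5
P	0.8
S	-2.5
T	-5.0
W	-7.9
Y	2.9
V	-10.9
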