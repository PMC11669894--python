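# GRAR740103 side-chain molecular volume (Grantham 1974)
residue	value
A	31.0
R	124.0
N	56.0
D	54.0
C	55.0
Q	85.0
E	83.0
G	3.0
H	96.0
I	111.0
L	111.0
K	119.0
M	105.0
F	132.0
P	32.5
S	32.0
T	61.0
W	170.0
Y	136.0
V	84.0
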