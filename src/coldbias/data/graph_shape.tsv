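amino_acid	graph_shape
A	1.0
C	1.77
D	1.6
E	1.56
F	2.58
G	0.0
H	2.99
I	1.83
K	1.89
L	1.7
M	2.35
N	1.6
P	2.7
Q	1.56
R	2.68
S	1.31
T	3.03
V	1.22
W	3.21
Y	2.7
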