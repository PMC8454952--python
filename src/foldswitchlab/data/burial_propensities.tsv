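# per-class burial well depths, kcal/mol (low, medium, high density)
res	low	medium	high
A	-0.300	-0.500	-0.700
C	-0.222	-0.500	-0.778
D	-0.889	-0.500	-0.111
E	-0.889	-0.500	-0.111
F	-0.189	-0.500	-0.811
G	-0.544	-0.500	-0.456
H	-0.856	-0.500	-0.144
I	-0.000	-0.500	-1.000
K	-0.933	-0.500	-0.067
L	-0.078	-0.500	-0.922
M	-0.289	-0.500	-0.711
N	-0.889	-0.500	-0.111
P	-0.678	-0.500	-0.322
Q	-0.889	-0.500	-0.111
R	-1.000	-0.500	-0.000
S	-0.589	-0.500	-0.411
T	-0.578	-0.500	-0.422
V	-0.033	-0.500	-0.967
W	-0.600	-0.500	-0.400
Y	-0.644	-0.500	-0.356
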