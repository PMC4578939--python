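# United-atom radii for heavy-atom-only structures (Chothia-type set):
# carbon/nitrogen radii are inflated to absorb the missing hydrogens.
# pattern	radius_nm
H	0.100
C	0.187
N	0.165
O	0.140
S	0.185
P	0.190
F	0.147
CL	0.175
BR	0.185
I	0.198
NA	0.227
MG	0.173
K	0.275
CA	0.231
ZN	0.139
FE	0.156
MN	0.161
CU	0.140
SE	0.190
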