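element	pb_radius_A
H	1.0
C	1.7
N	1.5
O	1.4
P	1.85
S	1.85
MG	1.45
NA	1.85
CL	1.75
K	2.03
MN	1.45
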