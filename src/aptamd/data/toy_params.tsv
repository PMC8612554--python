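residue_name	atom_name	charge_e	rmin_half_A	epsilon_kcal	pb_radius_A
LIG	C1	0.05	1.908	0.086	1.7
LIG	C2	0.05	1.908	0.086	1.7
LIG	C3	0.05	1.908	0.086	1.7
LIG	C4	0.05	1.908	0.086	1.7
LIG	C5	0.05	1.908	0.086	1.7
LIG	C6	0.05	1.908	0.086	1.7
LIG	C7	0.05	1.908	0.086	1.7
LIG	C8	0.05	1.908	0.086	1.7
LIG	C9	0.05	1.908	0.086	1.7
LIG	C10	0.05	1.908	0.086	1.7
LIG	C11	0.05	1.908	0.086	1.7
LIG	C12	0.05	1.908	0.086	1.7
LIG	N1	-0.35	1.824	0.17	1.5
LIG	H1	0.35	0.6	0.0157	1.0
LIG	O1	-0.45	1.6612	0.21	1.4
LIG	N2	-0.4	1.824	0.17	1.5
G	B1	0.02	1.908	0.086	1.7
G	B2	0.02	1.908	0.086	1.7
G	B3	0.02	1.908	0.086	1.7
G	B4	0.02	1.908	0.086	1.7
G	B5	0.02	1.908	0.086	1.7
G	B6	0.02	1.908	0.086	1.7
G	B7	0.02	1.908	0.086	1.7
G	B8	0.02	1.908	0.086	1.7
G	C1'	0.1	1.908	0.086	1.7
U	B1	0.02	1.908	0.086	1.7
U	B2	0.02	1.908	0.086	1.7
U	B3	0.02	1.908	0.086	1.7
U	B4	0.02	1.908	0.086	1.7
U	B5	0.02	1.908	0.086	1.7
U	B6	0.02	1.908	0.086	1.7
U	B7	0.02	1.908	0.086	1.7
U	B8	0.02	1.908	0.086	1.7
U	C1'	0.1	1.908	0.086	1.7
C	B1	0.02	1.908	0.086	1.7
C	B2	0.02	1.908	0.086	1.7
C	B3	0.02	1.908	0.086	1.7
C	B4	0.02	1.908	0.086	1.7
C	B5	0.02	1.908	0.086	1.7
C	B6	0.02	1.908	0.086	1.7
C	B7	0.02	1.908	0.086	1.7
C	B8	0.02	1.908	0.086	1.7
C	C1'	0.1	1.908	0.086	1.7
A	B1	0.02	1.908	0.086	1.7
A	B2	0.02	1.908	0.086	1.7
A	B3	0.02	1.908	0.086	1.7
A	B4	0.02	1.908	0.086	1.7
A	B5	0.02	1.908	0.086	1.7
A	B6	0.02	1.908	0.086	1.7
A	B7	0.02	1.908	0.086	1.7
A	B8	0.02	1.908	0.086	1.7
A	C1'	0.1	1.908	0.086	1.7
U	O4	-0.45	1.6612	0.21	1.4
C	N4	-0.3	1.824	0.17	1.5
C	H4	0.3	0.6	0.0157	1.0
C	C4	0.0	1.908	0.086	1.7
A	N6	-0.3	1.824	0.17	1.5
A	H6	0.3	0.6	0.0157	1.0
MG	MG	2.0	0.7926	0.00295	1.45
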