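# dmdpep coarse-grained bead parameter table, version 1
# aa	name3	sc_mass_amu	sc_radius_A	charge_e	kd_hydropathy
A	ALA	15.0	1.8	0	1.8
R	ARG	100.1	2.9	1	-4.5
N	ASN	58.1	2.3	0	-3.5
D	ASP	59.0	2.2	-1	-3.5
C	CYS	47.1	2.1	0	2.5
Q	GLN	72.1	2.5	0	-3.5
E	GLU	73.1	2.4	-1	-3.5
G	GLY	0.0	0.0	0	-0.4
H	HIS	81.1	2.6	0	-3.2
I	ILE	57.1	2.5	0	4.5
L	LEU	57.1	2.5	0	3.8
K	LYS	72.1	2.7	1	-3.9
M	MET	75.1	2.6	0	1.9
F	PHE	91.1	2.8	0	2.8
P	PRO	41.1	2.2	0	-1.6
S	SER	31.0	1.9	0	-0.8
T	THR	45.1	2.1	0	-0.7
W	TRP	130.2	3.0	0	-0.9
Y	TYR	107.1	2.9	0	-1.3
V	VAL	43.1	2.3	0	4.2
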