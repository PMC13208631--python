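# Kyte-Doolittle hydropathy index for the 20 canonical amino acids.
# Positive = hydrophobic, negative = hydrophilic.
three_letter	one_letter	hydropathy
ALA	A	1.8
ARG	R	-4.5
ASN	N	-3.5
ASP	D	-3.5
CYS	C	2.5
GLN	Q	-3.5
GLU	E	-3.5
GLY	G	-0.4
HIS	H	-3.2
ILE	I	4.5
LEU	L	3.8
LYS	K	-3.9
MET	M	1.9
PHE	F	2.8
PRO	P	-1.6
SER	S	-0.8
THR	T	-0.7
TRP	W	-0.9
TYR	Y	-1.3
VAL	V	4.2
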