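# Modified amino-acid residue codes mapped to their canonical parents.
# Residues absent from this table and from the 20 canonical codes are
# excluded from coordination spheres (and logged).
alias	parent
MSE	MET
SEC	CYS
CSO	CYS
CSD	CYS
CME	CYS
OCS	CYS
SEP	SER
TPO	THR
PTR	TYR
HYP	PRO
KCX	LYS
LLP	LYS
MLY	LYS
PYL	LYS
FME	MET
MLE	LEU
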