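# Metal-bearing chemical-component (ligand) codes recognised as Fe/Ni metal
# centres, with the metal class used for cohort assignment.
# metal_class: Fe = iron only; Ni = nickel only; FeNi = mixed NiFe centre.
code	description	metal_class
SF4	Fe4/S4 iron-sulfur cluster	Fe
FES	Fe2/S2 inorganic cluster	Fe
FE	Fe(III) ion	Fe
FE2	Fe(II) ion	Fe
FEL	hydrated Fe ion	Fe
F3S	Fe3-S4 cluster	Fe
F4S	Fe4-S3 cluster	Fe
SF3	Fe4-S3 cluster	Fe
6ML	oxygen-damaged SF4 cluster	Fe
FCO	carbon monoxide-(dicyano) iron	Fe
FSX	(aqua)(Glu-O)iron(II)	Fe
HC1	2Fe/2S/5-carbonyl/2-water inorganic cluster	Fe
HEC	2Fe/2S/3-carbonyl/2-cyanide/water/methyl-ether cluster	Fe
HEM	protoporphyrin IX with Fe (heme group)	Fe
NI	Ni(II) ion	Ni
3NI	Ni(III) ion	Ni
UWE	CNiO	Ni
F43	factor 430 (C42H51N6NiO13)	Ni
NFS	Fe4-Ni-S5 cluster	FeNi
BF8	Fe4-Ni-S5 cluster with oxygen	FeNi
RQM	Fe3-Ni-S4 cluster	FeNi
XCC	Fe4-Ni-S4 cluster	FeNi
WCC	Fe3-Ni-S4 cluster	FeNi
CUV	Fe4-Ni-S4 cluster, oxidized	FeNi
NFE	Ni-Fe active centre (C2HFeNiO3S2)	FeNi
NFV	Ni-Fe oxidized active centre (C3FeN2NiO2)	FeNi
NFU	Ni-Fe reduced active centre (C3HFeN2NiO)	FeNi
NFO	Ni-Fe oxidized active centre (C3H2FeNNiO3)	FeNi
FNE	C3FeNiO3S	FeNi
NWN	C3H4FeN2NiO	FeNi
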