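# Element-level hard/soft acid-base (HSAB) classification after Pearson.
# The classification is collapsed to one class per element, taken from the
# dominant mineral-forming oxidation state; edit this table to explore
# alternative assignments (e.g., Fe3+ as a hard acid). Classes:
# hard_acid, hard_base, soft_acid, soft_base, intermediate, none.
symbol	hsab_class
H	soft_base
Li	hard_acid
Be	hard_acid
B	hard_acid
C	soft_base
N	hard_base
O	hard_base
F	hard_base
Na	hard_acid
Mg	hard_acid
Al	hard_acid
Si	hard_acid
P	soft_base
S	soft_base
Cl	hard_base
K	hard_acid
Ca	hard_acid
Sc	hard_acid
Ti	hard_acid
V	hard_acid
Cr	hard_acid
Mn	hard_acid
Fe	intermediate
Co	intermediate
Ni	intermediate
Cu	intermediate
Zn	intermediate
Ga	hard_acid
Ge	intermediate
As	soft_base
Se	soft_base
Br	soft_base
Rb	hard_acid
Sr	hard_acid
Y	hard_acid
Zr	hard_acid
Nb	hard_acid
Mo	intermediate
Tc	intermediate
Ru	intermediate
Rh	intermediate
Pd	soft_acid
Ag	soft_acid
Cd	soft_acid
In	intermediate
Sn	intermediate
Sb	intermediate
Te	soft_base
I	soft_base
Cs	hard_acid
Ba	hard_acid
La	hard_acid
Ce	hard_acid
Pr	hard_acid
Nd	hard_acid
Sm	hard_acid
Eu	hard_acid
Gd	hard_acid
Tb	hard_acid
Dy	hard_acid
Ho	hard_acid
Er	hard_acid
Tm	hard_acid
Yb	hard_acid
Lu	hard_acid
Hf	hard_acid
Ta	hard_acid
W	intermediate
Re	intermediate
Os	intermediate
Ir	intermediate
Pt	soft_acid
Au	soft_acid
Hg	soft_acid
Tl	soft_acid
Pb	intermediate
Bi	intermediate
Th	hard_acid
Pa	hard_acid
U	hard_acid
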