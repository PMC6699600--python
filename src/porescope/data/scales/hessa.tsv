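# Hessa et al. (2005) Nature 433:377-381.
# Apparent free energy of membrane insertion via the Sec61 translocon,
# kcal/mol; negative values favor insertion (hydrophobic residues).
# higher_is_hydrophobic: false
ALA	0.11
ARG	2.58
ASN	2.05
ASP	3.49
CYS	-0.13
GLN	2.36
GLU	2.68
GLY	0.74
HIS	2.06
ILE	-0.60
LEU	-0.55
LYS	2.71
MET	-0.10
PHE	-0.32
PRO	2.23
SER	0.84
THR	0.52
TRP	0.30
TYR	0.68
VAL	-0.31
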