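# Element van der Waals radii in nm (Bondi, J. Phys. Chem. 68:441, 1964).
# Format: ELEMENT<ws>radius_nm  or  RESNAME<ws>ATOMNAME<ws>radius_nm.
# Lookup precedence: (residue, atom name) > element > default (0.15 nm).
H	0.120
C	0.170
N	0.155
O	0.152
F	0.147
P	0.180
S	0.180
CL	0.175
BR	0.185
I	0.198
NA	0.227
K	0.275
MG	0.173
ZN	0.139
SE	0.190
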