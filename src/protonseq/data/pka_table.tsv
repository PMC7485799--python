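code	name	carboxyl_pka	amine_pka	sidechain_pka
A	Alanine	2.35	9.87
C	Cysteine	2.05	10.25	8.00
D	Aspartic Acid	2.10	9.82	3.86
E	Glutamic Acid	2.10	9.47	4.07
F	Phenylalanine	2.58	9.24
G	Glycine	2.35	9.78
H	Histidine	1.77	9.18	6.10
I	Isoleucine	2.32	9.76
K	Lysine	2.18	8.95	10.53
L	Leucine	2.33	9.74
M	Methionine	2.28	9.21
N	Asparagine	2.02	8.80
P	Proline	2.00	10.60
Q	Glutamine	2.17	9.13
R	Arginine	2.01	9.04	12.48
S	Serine	2.21	9.15
T	Threonine	2.09	9.10
V	Valine	2.29	9.72
W	Tryptophan	2.38	9.39
Y	Tyrosine	2.20	9.11	10.07
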