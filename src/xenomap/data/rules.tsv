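rule_name	phase	smirks
aromatic_hydroxylation	I	[c;H1;$(c(:c)):1]>>[c:1]O
xanthine_c8_oxidation	I	[n:2]1[cH:1][n:3][c:4]2[c:5]1[c:6](=O)[n:7][c:8](=O)[n:9]2>>[N:2]1[C:1](=O)[N:3][C:4]2=[C:5]1[C:6](=O)[N:7][C:8](=O)[N:9]2
n_demethylation_aromatic	I	[n;X3:1][CH3]>>[nH:1]
n_demethylation_tertiary	I	[N;X3;$(N([CH3])([#6])[#6]);!$(NC=O):1][CH3]>>[N:1]
n_demethylation_secondary	I	[N;X3;H1;$(N([CH3])[#6]);!$(NC=O):1][CH3]>>[N:1]
o_demethylation	I	[O;X2;$(O([CH3])[#6]):1][CH3]>>[O:1]
benzylic_hydroxylation	I	[C;X4;H3:1][c:2]>>[C:1](O)[c:2]
aliphatic_hydroxylation	I	[C;X4;H2;$(C([CX4])[CX4]):1]>>[C:1]O
n_oxidation_azine	I	[n;X2:1]>>[n+:1][O-]
n_oxidation_tertiary_amine	I	[N;X3;$(N(C)(C)C);!$(NC=O):1]>>[N+:1][O-]
n_hydroxylation_arylamine	I	[N;X3;H2;$(Nc):1]>>[N:1]O
n_hydroxylation_secondary_arylamine	I	[N;X3;H1;$(N(c)[#6]);!$(NC=O):1]>>[N:1]O
alcohol_oxidation	I	[C;X4;H2:1][O;X2;H1:2]>>[C:1]=[O:2]
aldehyde_oxidation	I	[C;X3;H1:1]=[O:2]>>[C:1](O)=[O:2]
epoxidation	I	[C;!$(C=O):1]=[C;!$(C=O):2]>>[C:1]1[C:2]O1
s_oxidation	I	[S;X2;$(S([#6])[#6]):1]>>[S:1]=O
o_glucuronidation_phenol	II	[O;X2;H1;$(Oc):1]>>[O:1]C1OC(C(=O)O)C(O)C(O)C1O
o_glucuronidation_alcohol	II	[O;X2;H1;$(O[CX4]):1]>>[O:1]C1OC(C(=O)O)C(O)C(O)C1O
acyl_glucuronidation	II	[O;X2;H1;$(OC=O):1]>>[O:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_arylamine	II	[N;X3;H2;$(Nc):1]>>[N:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_aliphatic_amine	II	[N;X3;H2;$(N[CX4]):1]>>[N:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_azole	II	[n;H1:1]>>[n:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_secondary_arylamine	II	[N;X3;H1;$(N(c)[#6]);!$(NC=O):1]>>[N:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_secondary_amine	II	[N;X3;H1;$(N([CX4])[CX4]);!$(NC=O):1]>>[N:1]C1OC(C(=O)O)C(O)C(O)C1O
o_glucuronidation_n_hydroxy	II	[O;X2;H1;$(ON):1]>>[O:1]C1OC(C(=O)O)C(O)C(O)C1O
s_glucuronidation_thiol	II	[S;X2;H1:1]>>[S:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_amide	II	[N;X3;H1;$(NC=O):1]>>[N:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_hydrazine	II	[N;X3;H2;$(NN):1]>>[N:1]C1OC(C(=O)O)C(O)C(O)C1O
n_glucuronidation_tertiary_amine	II	[N;X3;$(N([CX4])([CX4])[CX4]):1]>>[N+:1]C1OC(C(=O)O)C(O)C(O)C1O
n_acetylation_arylamine	II	[N;X3;H2;$(Nc):1]>>[N:1]C(C)=O
n_acetylation_aliphatic_amine	II	[N;X3;H2;$(N[CX4]):1]>>[N:1]C(C)=O
n_acetylation_secondary_amine	II	[N;X3;H1;$(N([#6])[#6]);!$(NC=O):1]>>[N:1]C(C)=O
n_acetylation_hydrazine	II	[N;X3;H2;$(NN):1]>>[N:1]C(C)=O
n_acetylation_arylhydroxylamine	II	[N;X3;H1;$(N(c)O):1]>>[N:1]C(C)=O
o_sulfation_phenol	II	[O;X2;H1;$(Oc):1]>>[O:1]S(=O)(=O)O
o_sulfation_alcohol	II	[O;X2;H1;$(O[CX4]):1]>>[O:1]S(=O)(=O)O
n_sulfation_arylamine	II	[N;X3;H2;$(Nc):1]>>[N:1]S(=O)(=O)O
n_sulfation_aliphatic_amine	II	[N;X3;H2;$(N[CX4]):1]>>[N:1]S(=O)(=O)O
n_sulfation_secondary_amine	II	[N;X3;H1;$(N([#6])[#6]);!$(NC=O):1]>>[N:1]S(=O)(=O)O
o_sulfation_n_hydroxy	II	[O;X2;H1;$(ON):1]>>[O:1]S(=O)(=O)O
gsh_conjugation_epoxide	II	[C:1]1[C:2][O:3]1>>[C:1](SCC(NC(=O)CCC(N)C(=O)O)C(=O)NCC(=O)O)[C:2][O:3]
o_methylation	II	[O;X2;H1;$(Oc):1]>>[O:1]C
n_methylation_azole	II	[n;H1:1]>>[n:1]C
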