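name	smiles
caffeine	Cn1cnc2c1c(=O)n(C)c(=O)n2C
13X	Cn1c(=O)c2[nH]cnc2n(C)c1=O
17X	Cn1cnc2c1c(=O)n(C)c(=O)[nH]2
37X	Cn1cnc2c1c(=O)[nH]c(=O)n2C
1MX	Cn1c(=O)c2[nH]cnc2[nH]c1=O
3MX	Cn1c(=O)[nH]c(=O)c2[nH]cnc21
7MX	Cn1cnc2c1c(=O)[nH]c(=O)[nH]2
137U	O=C1N(C)C(=O)N(C)C2=C1N(C)C(=O)N2
13U	O=C1N(C)C(=O)N(C)C2=C1NC(=O)N2
17U	O=C1N(C)C(=O)NC2=C1N(C)C(=O)N2
37U	O=C1NC(=O)N(C)C2=C1N(C)C(=O)N2
1MU	O=C1N(C)C(=O)NC2=C1NC(=O)N2
3MU	O=C1NC(=O)N(C)C2=C1NC(=O)N2
7MU	O=C1NC(=O)NC2=C1N(C)C(=O)N2
AFMU	CC(=O)NC1=C(NC=O)NC(=O)N(C)C1=O
137TAU	CN(C=O)C1=C(N)N(C)C(=O)N(C)C1=O
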