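rule_name	enzyme_family
aromatic_hydroxylation	CYPs
xanthine_c8_oxidation	CYPs
n_demethylation_aromatic	CYPs
n_demethylation_tertiary	CYPs
n_demethylation_secondary	CYPs
o_demethylation	CYPs
benzylic_hydroxylation	CYPs
aliphatic_hydroxylation	CYPs
n_oxidation_azine	CYPs
n_oxidation_tertiary_amine	CYPs
n_hydroxylation_arylamine	CYPs
n_hydroxylation_secondary_arylamine	CYPs
alcohol_oxidation	CYPs
aldehyde_oxidation	CYPs
epoxidation	CYPs
s_oxidation	CYPs
o_glucuronidation_phenol	UGTs
o_glucuronidation_alcohol	UGTs
acyl_glucuronidation	UGTs
n_glucuronidation_arylamine	UGTs
n_glucuronidation_aliphatic_amine	UGTs
n_glucuronidation_azole	UGTs
n_glucuronidation_secondary_arylamine	UGTs
n_glucuronidation_secondary_amine	UGTs
o_glucuronidation_n_hydroxy	UGTs
s_glucuronidation_thiol	UGTs
n_glucuronidation_amide	UGTs
n_glucuronidation_hydrazine	UGTs
n_glucuronidation_tertiary_amine	UGTs
n_acetylation_arylamine	NATs
n_acetylation_aliphatic_amine	NATs
n_acetylation_secondary_amine	NATs
n_acetylation_hydrazine	NATs
n_acetylation_arylhydroxylamine	NATs
o_sulfation_phenol	SULTs
o_sulfation_alcohol	SULTs
n_sulfation_arylamine	SULTs
n_sulfation_aliphatic_amine	SULTs
n_sulfation_secondary_amine	SULTs
o_sulfation_n_hydroxy	SULTs
gsh_conjugation_epoxide	GSTs
o_methylation	EXCLUDED
n_methylation_azole	EXCLUDED
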