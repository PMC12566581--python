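name	delta	reaction_class	enabled
Mono-hydroxylation/oxidation	+O	oxidation	1
Di-hydroxylation	+O2	oxidation	1
Dehydrogenation	-H2	oxidation	1
Hydrogenation	+H2	reduction	1
Methylation	+CH2	other	1
N/O-Dealkylation/demethylation	-CH2	oxidation	1
Desulphuration	-S+O	oxidation	1
Epoxide-hydration	+H2O	hydrolysis	1
Deamination	-NH3+O	oxidation	1
Deamination (non-oxidative)	-NH3	other	0
Dehydroxylation/decarboxylation	-O	reduction	1
Decarboxylation	-CO2	other	1
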