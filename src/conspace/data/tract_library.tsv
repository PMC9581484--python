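name	abbreviation	category	bilateral	reverse_seeding
Arcuate fasciculus	AF	association	1	1
Frontal aslant tract	FA	association	1	0
Inferior fronto-occipital fasciculus	IFO	association	1	1
Inferior longitudinal fasciculus	ILF	association	1	1
Middle longitudinal fasciculus	MdLF	association	1	1
Superior longitudinal fasciculus 1	SLF1	association	1	0
Superior longitudinal fasciculus 2	SLF2	association	1	0
Superior longitudinal fasciculus 3	SLF3	association	1	0
Uncinate fasciculus	UF	association	1	0
Vertical occipital fasciculus	VOF	association	1	1
Anterior commissure	AC	commissural	0	1
Forceps major	FMA	commissural	0	1
Forceps minor	FMI	commissural	0	1
Middle cerebellar peduncle	MCP	commissural	0	1
Cingulum bundle: dorsal section	CBD	limbic	1	0
Cingulum bundle: perigenual section	CBP	limbic	1	0
Cingulum bundle: temporal section	CBT	limbic	1	0
Fornix	FX	limbic	1	0
Acoustic radiation	AR	projection	1	1
Anterior thalamic radiation	ATR	projection	1	0
Corticospinal tract	CST	projection	1	0
Optic radiation	OR	projection	1	1
Superior thalamic radiation	STR	projection	1	0
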