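protein	accession	wild_peptide	mutant_peptide	span	site	count	note
RAB2A	P61019	IQEGVFDIDNEANGIK	IQEGVFDINNEANGIK	P61019_171_186	D179N	4
CKAP4	Q07065	ITIQAITEK	IAIQAITEK	Q07065_347_355	T348A	2
VIM	P08670	IIEEMIQR	IQEEMIQR	P08670_189_196	I190E	1	printed alt E; peptide pair gives Q at 190
PABPC1	P11940	GFGFVCFSSPEDATK	GFGFVCFSSPEEATK	P11940_334_348	D345E	1
UQCRC1	P31930	ICTSVTESEVAR	ICTSATESEVAR	P31930_379_390	V383A	1
HNRNPM	P52272	INDIISNAIK	INEIISNAIK	P52272_372_381	D374E	1
ACTG2	P63267	CEEETTAPVCDNGSGICK	CEEETTAIVCDNGSGICK	P63267_2_19	P9I	1
LRG1	P02750	NAITGIPSGIFQASATIDTIVIK	NAITGIPPGIFQASATIDTIVIK	P02750_126_148	S133P	1
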