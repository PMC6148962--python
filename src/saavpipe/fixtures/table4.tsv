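protein	accession	wild_peptide	mutant_peptide	span	site	count	note
CCT6A	P40227	NAIDDGCVVPGAGAVEVAMAEAIIK	NAIDDGCVVPGAGAVEVAMAEAINK	P40227_400_424	I423N	4
CAT	P04040	NISVEDAAR	NISVEDVAR	P04040_244_252	A250V	2
ACTN1	P12814	VGWEQIITTIAR	VGWEQIITTITR	P12814_715_726	A725T	1
JUP	P14923	TMQNTSDIDTAR	TMQNTNDIDTAR	P14923_192_203	S197N	1
ARF4	P18085	HYFQNTQGIIFVVDSNDR	HYFQNTQGIIFVVDSDDR	P18085_80_97	N95D	1
FAM3D	Q96BQ1	AFDMYSGDVMHIVK	SFDMYSGDVMHIVK	Q96BQ1_118_131	A118S	1
HLA-B	P01889	FISVGYVDDTQFVR	FIAVGYVDDTQFVR	P01889_46_59	S48A	1
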