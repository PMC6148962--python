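protein	accession	wild_peptide	mutant_peptide	span	site	count	note
MYH9	P35579	AGVIAHIEEER	AGVITHIEEER	P35579_765_775	A769T	8
HSPA9	P38646	EQQIVIQSSGGISKDDIENMVK	EQQIVIQSSGGISNDDIENMVK	P38646_542_563	K555N	8
HSP90AB1	P08238	NPDDITQEEYGEFYK	NPDDITQDEYGEFYK	P08238_292_306	E299N	3	printed alt N; peptide pair gives D at 299
ATP2A2	P16615	DIVPGDIVEIAVGDK	DIVPGDNVEIAVGDK	P16615_144_158	I150N	3
FABP5	Q01469	ATVQQIEGR	TTVQQIEGR	Q01469_2_10	A2T	2
XPO1	O14980	NVDIIKDPETVK	NVDIIQDPETVK	O14980_675_686	K680Q	2
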