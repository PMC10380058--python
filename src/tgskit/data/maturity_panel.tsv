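# Maturity-timing SNP panel: 39 loci with GWAS effect sizes (beta) and
# per-group minor-allele frequencies (fractions) for 240 European controls
# (CON) and two academy footballer age phases (U12-16, U17-23).
# Allele letters are SYNTHETIC placeholders (earlier=A, later=G): the
# source publication does not print per-SNP effect-allele identities, which
# live in the upstream GWAS summary statistics. Real genotype data requires
# the user to supply true orientations via a custom panel file.
rsid	gene	beta	earlier_allele	later_allele	maf_CON	maf_U12-16	maf_U17-23
rs10980922	ZNF483	0.055	A	G	0.07	0.09	0.07
rs7402990	HERC2	0.051	A	G	0.10	0.08	0.11
rs35063026	C16orf55	0.051	A	G	0.07	0.09	0.10
rs1659127	MIR193B	0.050	A	G	0.34	0.30	0.25
rs11156429	LIN28B	0.049	A	G	0.45	0.26	0.26
rs9408817	TMEM38B	0.041	A	G	0.32	0.33	0.33
rs73182377	SOX2OT	0.040	A	G	0.28	0.26	0.32
rs6589961	C11orf63	0.038	A	G	0.43	0.41	0.39
rs62379978	PHF15	0.036	A	G	0.16	0.14	0.17
rs77578010	C1orf127	0.036	A	G	0.21	0.26	0.23
rs71578952	MKLN1	0.035	A	G	0.48	0.41	0.48
rs12203592	IRF4	0.035	A	G	0.12	0.19	0.12
rs4911442	NCOA6	0.029	A	G	0.10	0.17	0.13
rs2473234	PRDM2	0.029	A	G	0.15	0.11	0.18
rs17190166	DET1	0.028	A	G	0.42	0.47	0.43
rs17833789	AKAP1	0.028	A	G	0.44	0.40	0.46
rs2842385	MIR548A1	0.027	A	G	0.16	0.16	0.22
rs2049045	BDNF	0.027	A	G	0.21	0.20	0.16
rs11671893	ZNF536	0.026	A	G	0.18	0.12	0.14
rs10188334	TMEM18	0.025	A	G	0.19	0.17	0.22
rs6670873	SEC16B	0.025	A	G	0.20	0.17	0.16
rs9690350	PDGFA	0.025	A	G	0.41	0.42	0.49
rs438830	CYFIP2	0.025	A	G	0.21	0.24	0.14
rs3743266	RORA	0.024	A	G	0.36	0.32	0.36
rs2923177	ODZ2	0.023	A	G	0.45	0.48	0.48
rs1598656	SATB2	0.022	A	G	0.27	0.31	0.23
rs6925777	PRICKLE4	0.022	A	G	0.49	0.49	0.47
rs7853970	RMI1	0.022	A	G	0.47	0.42	0.45
rs767657	HPGDS	0.022	A	G	0.40	0.40	0.35
rs1121980	FTO	0.022	A	G	0.47	0.45	0.46
rs1514177	FPGT-TNNI3K	0.022	A	G	0.44	0.42	0.49
rs10934420	IGSF11	0.020	A	G	0.49	0.47	0.47
rs7896371	ADARB2	0.020	A	G	0.43	0.47	0.41
rs780094	GCKR	0.020	A	G	0.41	0.32	0.35
rs12940636	HLF	0.020	A	G	0.29	0.33	0.35
rs4801593	ZNF324B	0.020	A	G	0.27	0.26	0.28
rs11873906	DLGAP1	0.020	A	G	0.27	0.31	0.28
rs11190751	FAM178A	0.020	A	G	0.44	0.42	0.49
rs913588	KDM4C	0.019	A	G	0.44	0.42	0.47
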