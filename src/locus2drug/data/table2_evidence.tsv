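snp	gene	nearest	missense	eqtl	textmining	ppi_seed	somatic	ko_phenotype	functional	score	ambiguous
rs3217810	CCND2	1	0	1	1	0	1	1	1	5	0
rs10774214	CCND2	1	0	0	1	0	1	1	1	4	0
rs1321311	CDKN1A	1	0	1	1	0	0	1	1	4	0
rs4444235	BMP4	1	0	1	1	0	0	1	1	4	0
rs9929218	CDH1	1	0	0	1	0	1	1	1	4	0
rs10114408	BARX1	1	0	0	1	0	0	1	1	3	0
rs10411210	RHPN2	1	0	0	1	0	0	1	1	3	0
rs10911251	LAMC1	1	0	0	1	0	0	1	1	3	0
rs10911251	LAMC2	0	0	0	1	0	0	1	1	3	0
rs13130787	ATOH1	1	0	0	1	0	0	1	1	3	0
rs39453	CYCS	1	0	1	0	0	0	1	1	3	0
rs4813802	BMP2	1	0	0	1	0	0	1	1	3	0
rs4925386	LAMA5	1	0	1	1	0	0	0	1	3	0
rs4939827	SMAD7	1	0	0	1	0	0	1	1	3	0
rs59336	TBX3	1	0	0	1	0	0	1	1	3	0
rs647161	PITX1	0	0	0	1	0	0	1	1	3	0
rs7315438	TBX3	1	0	0	1	0	0	1	1	3	0
rs11169552	ATF1	0	0	0	0	0	1	1	0	2	0
rs11632715	GREM1	0	0	0	1	0	0	0	1	2	0
rs12548021	DUSP4	1	0	0	0	0	0	1	1	2	0
rs16969681	GREM1	0	0	0	1	0	0	0	1	2	0
rs17094983	DACT1	1	0	0	1	0	0	1	0	2	0
rs1912453	RGS4	0	0	0	0	0	0	1	1	2	0
rs1957636	CDKN3	1	0	0	1	0	0	0	1	2	0
rs2057314	ROS1	0	0	0	0	0	1	1	0	2	0
rs2057314	GOPC	1	0	0	0	0	1	0	1	2	0
rs367615	MAN2A1	1	0	0	0	0	0	1	1	2	0
rs3802842	C11orf53	0	0	0	1	1	0	0	0	2	0
rs4779584	GREM1	0	0	0	1	0	0	0	1	2	0
rs7758229	SLC22A3	1	0	0	0	0	0	1	1	2	0
rs8180040	PTPN23	0	1	0	0	0	0	0	1	2	0
rs8180040	PTH1R	0	0	0	0	0	0	1	1	2	0
rs8180040	SETD2	0	0	0	0	0	1	1	0	2	0
rs9365723	SYNJ2	1	0	1	0	0	0	0	1	2	1
rs9929218	CDH3	0	0	0	1	0	0	1	0	2	0
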