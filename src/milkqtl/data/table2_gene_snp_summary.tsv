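# Per-gene SNP summary for the 20 differentially expressed hub/bottleneck
# genes carrying nonsynonymous substitutions (caller-intersected,
# quality-filtered callset). bisnp_count = biallelic subset.
gene_id	symbol	chr	start	end	snp_count	bisnp_count
ENSBTAG00000007689	LPIN1	NC_040086.1	85168990	85299051	10	9
ENSBTAG00000009578	PTK2	NC_040089.1	2793205	2986179	1	1
ENSBTAG00000026356	DGAT1	NC_040089.1	547336	558673	2	2
ENSBTAG00000014357	SDC2	NC_040089.1	67885139	68006993	2	2
ENSBTAG00000008432	NUP98	NC_040090.1	32662235	32749000	2	2
ENSBTAG00000011266	ZBTB16	NC_040090.1	59519169	59723887	3	3
ENSBTAG00000005691	FGF2	NC_040092.1	37900967	37980582	2	2
ENSBTAG00000005091	DGKG	NC_040076.1	80595457	80821976	3	3
ENSBTAG00000016525	ITGA1	NC_040095.1	25934013	26116012	10	9
ENSBTAG00000001335	GHR	NC_040095.1	31683009	31993386	6	6
ENSBTAG00000003300	MFGE8	NC_040096.1	20516116	20540642	4	4
ENSBTAG00000021527	IGF1R	NC_040096.1	7856996	8161856	1	1
ENSBTAG00000027629	ANK1	NC_040102.1	36035255	36276595	5	4
ENSBTAG00000010660	CACNA1C	NC_040080.1	11268673	11659827	3	3
ENSBTAG00000031544	DDIT3	NC_040080.1	64346323	64350540	1	1
ENSBTAG00000020536	HERC6	NC_040081.1	36492384	36549974	9	9
ENSBTAG00000019716	CXCL8	NC_040081.1	88364933	88368713	1	1
ENSBTAG00000006240	TLR4	NC_040083.1	107075099	107086126	6	5
ENSBTAG00000012855	LPL	NC_040083.1	66717576	66744131	1	1
ENSBTAG00000048655	NT5E	NC_040084.1	64029657	64102659	6	6
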