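# Differentially expressed hub and bottleneck milk-fat QTL genes
# (Jersey vs Kashmiri orientation; raw p-values). 17 hub rows, 18
# bottleneck rows; 10 genes appear in both sections.
section	gene_id	symbol	log2fc	p_value	traits	description
hub	ENSBTAG00000008938	SRC	1.480587	0.002561	MFY;MPP;MPY;TDMY	SRC proto-oncogene, non-receptor tyrosine kinase
hub	ENSBTAG00000026356	DGAT1	0.921104	0.032625	MFP;MFY;MPP;MPY;MKCP;MY	Diacylglycerol O-acyltransferase 1
hub	ENSBTAG00000007867	STAT1	1.938208	0.0000648	MFP;MPP;MPY;MY	Signal transducer and activator of transcription 1
hub	ENSBTAG00000005691	FGF2	-1.55871	0.042228	MFY;MY	Fibroblast growth factor 2
hub	ENSBTAG00000019716	CXCL8	7.097327	0.000000000000077	MFY;MPP;MPY;TDMY	C-X-C motif chemokine ligand 8
hub	ENSBTAG00000006240	TLR4	3.918383	0.0000000123	MFP;MPP;MY	Toll like receptor 4
hub	ENSBTAG00000001335	GHR	-1.97171	0.02566	MFP;MFY;MPP;MPY;MY	Growth hormone receptor
hub	ENSBTAG00000012855	LPL	-1.61377	0.008224	MFP;MFY;MPP	Lipoprotein lipase
hub	ENSBTAG00000009578	PTK2	-0.97617	0.043672	MFP;MFY;MPP;MPY;MY	Protein tyrosine kinase 2
hub	ENSBTAG00000000546	ERBB2	-1.89535	0.048867	MFP;MFY;MPP;MPY;MY	Erb-b2 receptor tyrosine kinase 2
hub	ENSBTAG00000021527	IGF1R	1.798566	0.003947	MFP;MFY;MPP;MPY;MY	Insulin like growth factor 1 receptor
hub	ENSBTAG00000007476	BTRC	2.698919	0.0000384	MFY	Beta-transducin repeat containing E3 ubiquitin protein ligase
hub	ENSBTAG00000014357	SDC2	-1.96312	0.029226	MFP;MPP	Syndecan 2
hub	ENSBTAG00000048655	NT5E	-2.97069	0.000136	MFP;MFY;MPY	5'-nucleotidase ecto
hub	ENSBTAG00000007689	LPIN1	-2.38799	0.001822	MFP;MFY;MPP;MPY;TDMY	Lipin 1
hub	ENSBTAG00000003300	MFGE8	-1.90426	0.015698	MFP;MPP	Milk fat globule EGF and factor V/VIII domain containing
hub	ENSBTAG00000020536	HERC6	1.37883	0.00206	MFP;MFY;MPP;MPY	HECT and RLD domain containing E3 ubiquitin protein ligase family member 6
bottleneck	ENSBTAG00000026356	DGAT1	0.921104	0.032625	MFP;MFY;MPP;MPY;MKCP;MY	Diacylglycerol O-acyltransferase 1
bottleneck	ENSBTAG00000008938	SRC	1.480587	0.002561	MFY;MPP;MPY;TDMY	SRC proto-oncogene, non-receptor tyrosine kinase
bottleneck	ENSBTAG00000008432	NUP98	1.307627	0.033165	MFP	Nucleoporin 98 and 96 precursor
bottleneck	ENSBTAG00000027629	ANK1	-2.3949	0.000752	MFY;MPY	Ankyrin 1
bottleneck	ENSBTAG00000011266	ZBTB16	-1.84946	0.011504	MFY	Zinc finger and BTB domain containing 16
bottleneck	ENSBTAG00000016525	ITGA1	-2.10583	0.004815	MFY;MPP;MPY;MY	Integrin subunit alpha 1
bottleneck	ENSBTAG00000019716	CXCL8	7.097327	0.000000000000077	MFY;MPP;MPY;TDMY	C-X-C motif chemokine ligand 8
bottleneck	ENSBTAG00000007867	STAT1	1.938208	0.0000648	MFP;MPP;MPY;MY	Signal transducer and activator of transcription 1
bottleneck	ENSBTAG00000000546	ERBB2	-1.89535	0.048867	MFP;MFY;MPP;MPY;MY	Erb-b2 receptor tyrosine kinase 2
bottleneck	ENSBTAG00000007476	BTRC	2.698919	0.0000384	MFY	Beta-transducin repeat containing E3 ubiquitin protein ligase
bottleneck	ENSBTAG00000010106	CCND3	-1.78227	0.000135	MFP;MPP;MPY;MY	Cyclin D3
bottleneck	ENSBTAG00000001335	GHR	-1.97171	0.02566	MFP;MFY;MPP;MPY;MY	Growth hormone receptor
bottleneck	ENSBTAG00000006240	TLR4	3.918383	0.0000000123	MFP;MPP;MY	Toll like receptor 4
bottleneck	ENSBTAG00000010660	CACNA1C	-2.82445	0.0000723	MFY	Calcium voltage-gated channel subunit alpha1 C
bottleneck	ENSBTAG00000012855	LPL	-1.61377	0.008224	MFP;MFY;MPP	Lipoprotein lipase
bottleneck	ENSBTAG00000031544	DDIT3	2.367342	0.0000047	MFP;MFY;MPP;MPY;MY	DNA damage inducible transcript 3
bottleneck	ENSBTAG00000005091	DGKG	4.032464	0.000000442	MFP;MPP;MY	Diacylglycerol kinase gamma
bottleneck	ENSBTAG00000048655	NT5E	-2.97069	0.000136	MFP;MFY;MPY	5'-nucleotidase ecto
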