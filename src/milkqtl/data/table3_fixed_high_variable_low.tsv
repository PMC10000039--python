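# nsSNP genotypes of 14 indigenous cattle (8 high-, 6 low-milk-yield) at
# the 14 sites fixed in the high-yield group and variable in the low-yield
# group. Transcribed verbatim, including the LPIN1 85211528 Pulikulam C/T
# genotype whose T allele lies outside the declared REF/ALT pair.
# chrom joined from the per-gene summary table; "-" = missing call.
gene	chrom	pos	ref	alt	protein_change	Sahiwal 1	Sahiwal 2	Sahiwal 3	Sahiwal 4	Gir 1	Gir 2	Gir 3	Gir 4	Amritmahal	Dangi	Gaolao	Deoni	Pulikulam	Hallikar
GHR	NC_040095.1	31685773	C	G	392(G/A)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/G	C/G	C/C	C/G	C/C
GHR	NC_040095.1	31685984	A	G	462(N/D)	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/G	A/A	A/A	A/A	A/A
TLR4	NC_040083.1	107083326	A	C	151(A/T)	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/C	A/C	A/C	A/A	A/A
TLR4	NC_040083.1	107083914	C	A	347(N/G)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/A	C/C	C/C	C/C	C/C
LPIN1	NC_040086.1	85187074	G	A	772(R/K)	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/A	G/G	G/G	G/G	G/A	G/A
LPIN1	NC_040086.1	85209309	C	T	631(A/E)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/T	C/C	C/C	C/C
LPIN1	NC_040086.1	85211528	C	G	542(R/P)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/G	C/C	C/G	C/T	C/G
CACNA1C	NC_040080.1	11271411	C	T	204(E/K)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/T	C/C	C/C
ZBTB16	NC_040090.1	59717709	C	T	393(V/M)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/T	C/C	C/T	C/C	C/C
ITGA1	NC_040095.1	25983121	C	T	588(V/M)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/T	C/C
ANK1	NC_040102.1	36054194	G	A	111(P/S)	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/A	G/G
ANK1	NC_040102.1	36076037	G	A	127(R/H)	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/A
NT5E	NC_040084.1	64035090	C	T	475(C/F)	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	T/T	C/C	C/C	C/C
NT5E	NC_040084.1	64065719	G	A	151(A/V)	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/A	G/G	G/G
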