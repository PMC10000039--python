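# nsSNP genotypes of the same 14 animals at the 10 sites reported as fixed
# in the low-yield group and variable in the high-yield group. Transcribed
# verbatim, including the anomalous ZBTB16 59718206 column where Hallikar
# is A/A inside the nominally fixed low-yield group (the stated rule
# classifies that site variable-in-both; see docs/methods.md).
# chrom joined from the per-gene summary table; "-" = missing call.
gene	chrom	pos	ref	alt	protein_change	Sahiwal 1	Sahiwal 2	Sahiwal 3	Sahiwal 4	Gir 1	Gir 2	Gir 3	Gir 4	Amritmahal	Dangi	Gaolao	Deoni	Pulikulam	Hallikar
MFGE8	NC_040096.1	20518217	A	T	328(S/R)	A/A	A/A	A/A	A/A	A/T	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A
FGF2	NC_040092.1	37920746	G	A	19(G/R)	G/G	G/G	G/A	-	-	-	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
TLR4	NC_040083.1	107080326	G	A	67(R/K)	G/A	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
LPIN1	NC_040086.1	85205642	T	G	766(S/P)	T/T	T/G	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T
NUP98	NC_040090.1	32707374	G	A	548(H/Y)	G/G	G/G	G/A	G/A	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
PTK2	NC_040089.1	2973942	A	C	904(D/A)	A/A	A/A	A/A	A/A	A/A	A/A	A/C	A/A	A/A	A/A	A/A	A/A	A/A	A/A
ZBTB16	NC_040090.1	59717979	T	C	598(G/R)	T/T	T/T	T/T	T/T	T/T	T/T	T/C	T/T	T/T	T/T	T/T	T/T	T/T	T/T
ZBTB16	NC_040090.1	59718206	G	A	627(A/V)	G/G	G/G	G/A	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	A/A
DDIT3	NC_040080.1	64346576	C	T	87(S/L)	C/T	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C
NT5E	NC_040084.1	64102580	G	T	8(T/N)	G/G	G/T	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
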