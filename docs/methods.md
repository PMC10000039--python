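# Methods

## The inference chain

The pipeline prioritizes candidate milk-fat genes in three narrowing
steps and then asks a population-genetic question about them. QTL
annotations give a large trait-linked gene universe; protein-interaction
topology picks out the genes that either interact broadly (hubs, high
degree) or connect otherwise separate clusters (bottlenecks, high
betweenness); differential expression between a high-fat and a low-fat
breed keeps the subset whose transcription actually differs. The final
step screens whole-genome genotypes of two breed groups — 8 high-yield
animals (Sahiwal, Gir) and 6 low-yield animals (one each of six breeds)
— for amino-acid-changing SNPs that are *fixed* in one group while
*variable* in the other. Such sites are the candidates for breed-level
differences in milk fat.

## Set algebra

Trait–gene tables carry one row per association, so the same gene recurs
under several traits. Deduplication merges trait sets by union, keyed on
the raw, case-sensitive identifier (no symbol-to-ID mapping is
attempted); merging rather than dropping keeps dedup order-independent
and idempotent. Venn counts are exact set cardinalities;
`exclusive_trait_genes` uses strict set equality, so a gene annotated
for any extra trait does not count as "associated with these traits
only".

## Network prioritization

Edges below the combined-score threshold (default 0.5) are dropped
before the graph exists, so a node attached only by weak edges never
enters the node set. Scores in (1, 1000] are auto-detected as millesimal
STRING convention and divided by 1000. The graph is simple and
undirected: self-loops are dropped and duplicate pairs collapse to the
maximum score. Scores are used *only* for thresholding — shortest paths
are unweighted, since nothing in the underlying design weights paths.

Betweenness follows one fixed convention, because tools disagree:
unnormalized node betweenness with endpoints excluded and each unordered
pair counted once (networkx `normalized=False` on an undirected graph;
Brandes' algorithm). Tests verify it against an explicit
all-geodesic-enumeration oracle on random graphs of ≤ 8 nodes.

Top-k selection sorts by the metric descending with ties broken by gene
identifier ascending, making rank-k cuts reproducible; how the original
ranking cut ties is not documented anywhere, so determinism was chosen
over guesswork. "Bottleneck" has two readings in the field — pure
betweenness ranking versus ranking within the top 20% of the degree
distribution. `prioritize` supports both: an optional
`degree_percentile_prefilter` restricts bottleneck candidates to nodes
at or above the (1 − f) degree quantile. The library function defaults
to no prefilter (so a low-degree bridge node with maximal betweenness is
still a bottleneck); the pipeline config exposes the 0.20 default for
the stricter reading. With f = 1.0 the two coincide.

## DE integration

The DE table (gene, log₂ fold change, p-value) comes from an upstream
count-model fit and is consumed, not refit. Filtering is strict
(p < alpha, default 0.05) on raw p-values, matching the convention of
the reference tables; an optional Benjamini–Hochberg mode exists but is
off by default. Integration keeps DE genes inside the hub ∪ bottleneck
union, flags membership, and counts directions by the sign of log₂FC
(exactly zero counts as neither).

## Variant annotation

Coordinates are 1-based inclusive throughout (VCF convention). The
quality filter keeps SNP sites with QUAL strictly above 20; sites
without a QUAL value pass (caller-intersected inputs may lack one).
Caller intersection keys on (chrom, pos, ref, sorted alt set) and takes
genotypes from the first callset. Multi-allelic SNPs survive SNP
counting (the per-gene summary distinguishes total from biallelic
counts) but are excluded from effect annotation and the fixation screen,
which are biallelic by construction.

Effect annotation uses one transcript per gene: ordered, non-overlapping
CDS segments whose total length must be divisible by 3. The genomic
position maps to a spliced-CDS offset, reverse-complemented for minus-
strand models; the containing codon is translated for both alleles with
the standard nuclear code. ref_aa = alt_aa is synonymous; an
alt stop is STOP_GAINED (never counted as nonsynonymous); a lost stop is
STOP_LOST; sites outside the CDS are NONCODING. The genome's plus-strand
base must equal REF or the call errors out. Protein changes render as
`pos(Ref/Alt)`, e.g. `392(G/A)`.

## Fixation screen

A group is **fixed** at a site when at least `min_called` of its animals
are called and every called animal is homozygous for the same allele — a
uniformly heterozygous group is *not* fixed, matching how every fixed
cell in the reference tables is printed (always `X/X`). **Variable** is
defined relative to the other group's fixed homozygote and is
allele-agnostic: a genotype carrying an allele outside the declared
REF/ALT pair (the tables contain one such cell) still counts as
variable. Classification: both groups below the floor →
`INSUFFICIENT_DATA`; both fixed → concordant or discordant by allele
equality; one fixed → fixed-in-that-group/variable-in-the-other (when
one group is fixed and the other is not, the other necessarily shows a
differing genotype — asserted, not assumed); neither fixed →
`VARIABLE_BOTH`.

`min_called = 2` by default: the reference data classify one site with
only 5 of 8 high-group animals called, so the rule must tolerate
missingness, but a single called animal is too weak to declare fixation.
Missing genotypes are `./.` in VCF and `-` in table fixtures.

One reference column (ZBTB16 g.59718206) contains an `A/A` animal inside
its nominally fixed group; under the stated rule the site is
`VARIABLE_BOTH`, and the packaged fixture keeps the printed genotypes
rather than special-casing the column. Masking a genotype can
legitimately reclassify a site (removing a group's only variant
carrier makes the group fixed), so the invariance that holds — and is
tested — is: masking a call whose genotype remains represented in its
group either preserves the category or degrades it to
`INSUFFICIENT_DATA`.

## Synthetic data

The generators emulate the study's input shapes with known truth; all
four draw independent streams from one seed and are byte-reproducible.

* **Universe** (default 600 genes): realizes the MFY/MFP Venn structure
  exactly — defaults (161, 125, 131), i.e. 286 fat-yield and 256
  fat-percentage genes sharing 125, union 417. Genes outside the union
  carry other milk-trait codes; union genes pick up extra codes with
  probability 0.4.
* **Network** (default 403 nodes / 671 edges, 10 planted hubs): hub
  degrees are fixed first at ~4× the mean degree, and every other node
  is capped strictly below them, so top-k-by-degree recovery of the
  planted hubs is a construction guarantee; the rest grows as a
  preferential-attachment tree densified with degree-biased extra edges
  to the exact edge count. Scores are uniform on [0.5, 1]. A handful of
  nodes may end isolated (and thus absent), so the node count
  approximates the configured 403.
* **DE table**: targets get |log₂FC| ~ N(2.5, 0.8) with random sign —
  inside the 0.9–7.1 magnitude range of the reference gene table — and
  log-uniform p-values in [1e-8, 1e-3]; background genes get
  N(0, 0.5) effects and uniform p-values. Target recall at p < 0.05 is
  ≥ 0.95 by design.
* **Cohort** (default 8 HIGH + 6 LOW samples, mirroring the study):
  random 60 kb genome, 20 non-overlapping one- or two-segment gene
  models on random strands, and one planted biallelic coding SNP per
  requested category (defaults mirror the reference tables: 14
  fixed-high/variable-low, 9 fixed-low/variable-high, 1 variable-both).
  Alternate alleles are chosen to be amino-acid-changing by the
  generator's own codon bookkeeping, which shares no coordinate-mapping
  code with the annotator. Variable groups get 1..n−1 heterozygous
  carriers; missingness (default rate 0.02, matching the ~2% of missing
  cells in the reference tables) never touches carrier calls and never
  drops a group below `min_called`, so planted categories survive
  masking by construction. VCFs are written with QUAL ~ U(30, 60).

What the simulator does **not** model: linkage between sites, realistic
allele-frequency spectra, within-breed substructure, genotyping error,
read-level evidence, or isoform complexity. Passing recovery tests
therefore shows the classifier implements its categorical rule exactly —
not that the rule is robust to callset noise in real cohorts.

## Problem sizes and numerics

Tests run the exhaustive betweenness oracle on graphs of ≤ 8 nodes,
classifier recovery over 20 seeds × 9 planted sites, and cohort
simulations on 20–30 kb genomes with 6–10 genes; the full suite and the
acceptance script each finish in seconds. The genome-scale published
numbers (tens of millions of SNPs; the full interaction-network
snapshot) require the raw WGS/RNA-seq cohort and a database snapshot
that are not distributable, so the package substantiates those stages by
oracle equality and planted-truth recovery instead, and reproduces every
count that the packaged reference tables determine.

Floating-point notes: VCF QUAL survives a round-trip only to float32
precision; betweenness comparisons use relative tolerance; all rankings
and reports are deterministic given inputs and seed.
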