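# Methods

`phageome` re-implements, as a tested pipeline, an eco-evolutionary
analysis of a gut phage community sampled longitudinally alongside host
(animal) feeding behaviour. The pipeline runs from screened phage
genome sequences to population-level ecology: viral operational
taxonomic unit (vOTU) construction, lifestyle-resolved abundance
dynamics across feeding seasons, phage–prokaryote host linkage,
protein-cluster gene sharing as a horizontal-gene-transfer (HGT) proxy,
and intrapopulation SNP turnover. Because the motivating datasets are
raw sequencing deposits, every stage is exercised on synthetic data
with planted ground truth; this note records the models, the defaults,
and what the synthetic conditions do and do not establish.

## Screening and lifestyle

Screening consumes annotation summaries (the pipeline does not re-run
viral detection or gene calling). A contig is kept as a phage candidate
iff it has ≥ 1 viral gene, or no viral gene and either no host gene or
more than two hallmark genes. The rule is deliberately literal:
"hallmark > 2" means ≥ 3. It is monotone in viral evidence, which the
suite checks as a property.

Stop-codon reassignment is common in gut phages, so contigs longer than
10 kb with GC < 50% may be assigned an alternative genetic code
(4: TGA→Trp, 25: TGA→Gly, 15: TAG→Gln, 91: TAA→Gln) when that code's
total coding score is the maximum and at least 1.10× the standard-code
score. Ties keep code 11 (conservative; the criterion does not
disambiguate). Recoded contigs must re-validate (≥ 1 hallmark protein
or ≥ 50% of genes hitting phage references) or they are dropped. A
genome's assigned code is honoured later when classifying substitutions
as synonymous or not.

Lifestyle: prophages are temperate by definition; episomal genomes take
the classifier's virulent/temperate label. Supplying an episomal label
for a prophage is an input error, not a silent override.

## vOTU construction

Pairwise ANI is aggregated from local-alignment fragments: fragments
are taken in decreasing bit-score order, each contributes only where it
covers query bases not covered by a better fragment, and identity is
weighted by that novel length. Aligned fraction (AF) is the merged
covered length over genome length. Clustering is greedy centroid:
genomes visited longest-first (ID breaks ties, for determinism), each
joining the first seed with ANI ≥ 95% and AF ≥ 85%. The AF test is
applied to the **shorter** genome of the pair — the criterion names a
single "alignment fraction" without saying which genome, and requiring
the shorter genome's coverage is the permissive, common reading; the
per-genome AFs are both computed and stored, so the stricter
both-genomes rule is a one-line change.

Clusters are split into sub-populations by member source (VM: virus-like
particle enriched metagenome; MM: bulk microbial metagenome) and by
lifestyle; a cluster containing both values yields two sub-populations
sharing the vOTU id, so the tallies obey
`|A-subpops| + |B-subpops| − |dual clusters| = |clusters|` — an
invariant checked on random splits and on printed tallies.

## Abundance

A population's abundance in a sample is the trimmed mean ("tpmean") of
per-base depth over its representative genome: the `floor(0.05·L)`
lowest- and highest-depth positions (by rank, not contiguous windows —
the rank reading matches the coverage tool the convention comes from)
are discarded before averaging. Read alignments feeding depth are kept
at ≥ 95% identity over ≥ 75% of the read. Community analyses use
Hellinger-standardised matrices (square root of per-sample relative
abundance; unit sum of squares per sample). Protein-cluster abundance
is the summed abundance of the *distinct* populations encoding a member
protein, which keeps PC abundance phage-derived and invariant to
paralog counts.

## Feeding seasons and diet response

Daily diet profiles are the proportion of full-day feeding time per
food type (fruit, leaf, flower, animal, other); overlapping bouts in
one individual-day are rejected. Season assignment is agglomerative
clustering (Ward linkage, Euclidean metric — the source method names
only "hierarchical clustering"; both are configurable) cut at k = 2,
with the higher-mean-fruit cluster labelled HF (high-fruit) and the
other HL (high-leaf). Profiles are clustered jointly across
individual-dates; a per-individual variant would only matter when
individuals disagree about season timing, which the generator does not
model.

Diet response is a two-sided unpaired Wilcoxon rank-sum test per
population between seasons (exact null for small tie-free groups,
normal approximation with tie and continuity correction otherwise;
constant series give p = 1 by convention), BH-adjusted within one
individual × lifestyle — that family matches how responsive populations
are presented per animal and lifestyle. Responsive means q < 0.05.
Abundance variation is mean(HL) − mean(HF), aggregated over host
families by summation for linked populations.

## Host linkage

Two evidence routes, aggregated genome→population by the union rule
(one linking member suffices):

- **CRISPR spacers**: exact, full-length, zero-mismatch occurrence of
  the spacer (≥ 20 nt, ACGT only) in a phage genome on either strand.
  Exact matching *is* the criterion; the conventional BLAST E-value
  (≤ 1e-10) is carried in the config for provenance only.
- **Genome homology**: E-value ≤ 1e-3, bit score ≥ 50, alignment
  ≥ 1 kb, identity ≥ 96%, all inclusive at the boundary.

Derived statistics: host range (distinct prokaryote populations per
phage population) and phage range (distinct phage populations per
prokaryote, split by lifestyle; a prokaryote linked to both lifestyles
appears in both groups), per-link Pearson abundance correlations with
BH adjustment, and anti-phage defense burden (system *instances* summed
per genome; counting distinct types instead is a switch).

## Gene sharing (HGT proxy)

Proteins are clustered greedily, longest first, each sequence joining
the **best** qualifying cluster (highest identity to the
representative) at ≥ 60% identity covering ≥ 80% of the shorter
sequence, else founding a new cluster. Identity is matches over
alignment columns from an exact local alignment (BLOSUM62, gap open
11 / extend 1); no k-mer seeding heuristics are reproduced, only the
threshold semantics. A PC containing phage- and prokaryote-origin
proteins is *shared*; a phage genome's sharing ratio is its shared PCs
over its total PCs (distinct-PC counting). Prokaryote proteins on
prophage-flagged contigs must be excluded upstream so prophage genes do
not pose as HGT.

Host-vs-nonhost comparison: per phage–prokaryote pair, the fraction of
the phage population's PCs present in that prokaryote (normalised by
the phage's PC total, following the defining sentence; union
normalisation would be the alternative). Nonhost pairs (same phages,
family-matched unlinked prokaryotes) are subsampled without replacement
to the family's host-pair count under the run seed.

## SNP turnover

Variants are (position, alternative base) pairs passing quality > 30,
≥ 4 supporting reads and frequency > 1% (strict inequalities, as the
thresholds are printed); multi-allelic sites give independent records;
frequency is excluded from variant identity because sharedness is
set-based. Genomes qualify per individual only at ≥ 10× tpmean coverage
in *every* sample of that individual. Genome similarity between dates
is |earlier ∩ later| / |earlier|; each date is compared with all
subsequent dates. Per lifestyle, similarity is regressed on lag (OLS,
adjusted R²) and lifestyles are compared per lag bin with rank-sum
tests. Under a constant per-day loss probability ρ the expected
fraction at lag t is (1−ρ)^t, so `fit_turnover_rate` regresses
log(mean fraction) on lag through the origin and reports ρ = 1−e^slope.

## Shared statistics

Bray-Curtis, classical-scaling PCoA (negative eigenvalues reported,
their axes dropped), one-factor PERMANOVA in the adonis formulation
with permutation p = (1 + #{F* ≥ F}) / (1 + n_perm), Mantel, and
step-up BH. One numerical convention: with perfect group separation the
observed pseudo-F is infinite and every permutation that merely redraws
the same partition is equally infinite; the implementation reports the
+1-corrected minimum p in that degenerate case rather than counting
partition redraws as exceedances.

## Synthetic data: what it emulates and what it does not

The generator plants truth for every stage. Populations descend from
independent random ancestors by i.i.d. substitution (no indels), so ANI
is analytic: members mutated at rate d share expected identity
(1−d)² + d²/3 ≈ 96.05% at the default d = 0.02, safely above the 95%
threshold at 15 kb, while distinct ancestors sit near 25%. Genes are
tiled ORFs planted stop-free; member mutations occasionally reintroduce
stops, which protein extraction replaces with alanine (these are random
stand-ins, not biological ORFs). Spacers are verbatim 25–45 nt copies
from member genomes (either strand), shared genes are verbatim
nucleotide copies of annotated phage genes into host genomes, and a
*background* sharing mode copies genes into hosts irrespective of
assignment for null experiments. Abundance is lognormal
(μ = 3, σ = 0.7 base; σ = 0.3 sample noise) with responsive populations
multiplied by the seasonal effect in HL (virulent up, temperate down by
the inverse — the directionality of interest); per-base depth is
Poisson. Feeding bouts give the dominant food 72–88% of daily feeding
time. SNP series lose each variant with lifestyle-specific daily
probability and replace losses at fresh positions, keeping site counts
constant. Effect-size distributions for responsive populations are not
published quantities, so the generator exposes them as parameters
rather than claiming matched defaults.

None of this emulates real genome architecture, recombination,
amplification bias, alignment noise, or compositional sequencing
effects. Passing tests therefore establish that the *decision rules and
statistics* behave as specified under their own assumptions — exact
recovery when divergence bands are respected, calibrated error rates
under the null, power under planted effects — not that the pipeline is
robust to upstream bioinformatic noise.

## Problem sizes and numerical choices

Default pipeline scale (the package's own choice of a desk-scale
configuration): 20 vOTUs × 3 members × 15 kb, 6 hosts, one individual ×
two seasons × 6 dates, 8 SNP dates; a full run takes ~20 s. The
calibration suites use 200 null replicates (60 populations, 8+8
samples) for diet-response error control, 100 replicates for power and
turnover recovery, and 200×999 permutations for PERMANOVA calibration.
Determinism: every stochastic step draws from `numpy` Generators seeded
from the run seed; equal seeds give byte-identical tabular outputs.
Tie-breaks are lexicographic throughout (seed ordering, representative
selection). Degenerate inputs follow the conventions above (all-zero
samples preserved with warnings, empty earlier SNP profiles give an
undefined fraction, constant series are excluded from correlations).

## Known limitations

Single-factor PERMANOVA only; no stratified designs. The exact local
aligner is quadratic — protein clustering is meant for toy-to-moderate
scales, not hundreds of thousands of genes. Host linkage assumes
population labels for prokaryotes are given (dereplication is out of
scope). Read mapping, assembly and the upstream classifiers are
consumed as inputs, never re-implemented.
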