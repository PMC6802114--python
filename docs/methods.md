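# Methods

This note documents the models, algorithms and numerical choices behind
radforge, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## The experimental design being modelled

Paired-end RAD-Seq anchors forward reads at restriction sites (EcoRI,
G^AATTC), so a locus's forward reads are near-identical over their first
~100 bp, while each reverse read comes from an individually sheared molecule
and starts at a different distance from the cut site. Two consequences drive
the pipeline design:

1. molecules shorter than the read length put adapter sequence at the 3' end
   of *both* mates, starting exactly at the insert length;
2. reverse reads tile a staggered window downstream of the cut site, so a
   locus's reverse reads assemble into a contig several times longer than one
   read, which may or may not reach back far enough to overlap the forward
   contig.

## Adapter read-through scan

The probe is the first `probe_size` (default 50) bases of one mate; the other
mate is reverse-complemented so both share orientation, and the probe is slid
from the 3'-most alignment toward 5' in 1 bp steps. The first offset with
Hamming distance <= `max_distance` (default 5) wins — equivalently the longest
candidate insert, which protects against chance matches deep inside the read.
The boundary is the inferred insert length; both mates are truncated to it.

Numerical choices: the scan is run in both directions (forward probe against
reverse read and vice versa); when errors make the two boundaries disagree,
the smaller is used (conservative removal). N counts as a mismatch. Pairs
trimmed below 30 bp are discarded as unusable for clustering. Inserts shorter
than the probe are undetectable by construction; with a 50 bp probe and a 0.5%
error rate, the expected probe-to-target distance at the true offset is ~0.5,
so the threshold of 5 recovers essentially every true boundary while a chance
match (expected distance 37.5) never qualifies.

## Clustering model

Forward reads are cut to 85 bp and clustered per individual: exact piles with
depth >= `min_stack_depth` (3) seed stacks, seeds within `max_stack_mismatches`
(2) form one locus (its alleles), and shallower piles attach to the nearest
locus within the same budget or are discarded as error singletons. Loci match
across individuals by single-linkage within `max_locus_mismatches` (3).
Because single linkage can chain, cluster diameter is capped at twice that
budget and over-wide chains are split by a deterministic k-medoids on Hamming
distance. Consensus is a per-column majority with alphabetic tie-break.
"Highly repetitive" catalog tags are removed by a depth-outlier rule — total
depth above `repeat_depth_factor` (3.0) times the median — the simplest rule
consistent with a unimodal expected depth distribution; it is a stand-in, not
a reconstruction of any particular tool's internal criterion.

## Assembly and merging

The forward contig is a stacked majority consensus (reads are anchored, so no
alignment is needed); columns covered by fewer than two reads are dropped.
The reverse contig comes from a small greedy overlap-layout-consensus
assembler: candidate overlaps are located by 12-mer seeds from read prefixes,
verified at >= 80% identity over >= 16 bp, and merged best-first while
accumulating per-column base votes, so the final consensus uses the full
coverage rather than pairwise choices. Support fractions are reads consistent
with (forward, >= 80% identity) or incorporated into (reverse) the contig;
tags below 10% forward or 60% reverse support are skipped.

Merging aligns the forward contig with the reverse-complemented reverse
contig by global Needleman–Wunsch with free end gaps (the contigs overlap
only at their facing ends). Scoring is match +5, mismatch −4, linear gap −8.
The match score and the acceptance thresholds (score > 50, identity — the
count of exactly matching columns — > 10, score/identity > 4, and both 10 bp
contig ends preserved in the splice) define the merge rule; the ratio
threshold demands that at least ~80% of the score comes from matches. The gap
penalty is set to −8 rather than a softer value because with match +5 a gap
cost at or below ~5 puts the free-end-gap alignment of *random* flanks into
the linear (LCS-like) phase: the optimum meanders through chance matches,
inflating identity and making the ratio rule reject genuinely overlapping
pairs. At −8 the clean-overlap alignment is the optimum in all randomized
trials we ran (flanks up to 300/500 bp), and an exact overlap of length L
still scores exactly 5L. Mismatched overlap columns are resolved in favour of
the contig with higher read support. Non-merging pairs are joined with
exactly ten N; the pseudomolecule joins final contigs with exactly one
hundred N in stable tag order, with an index mapping global to contig-local
(1-based) coordinates.

## Nucleotide diversity

Per-site pi uses allele counts, not frequencies:
`pi = 1 - sum_a c_a (c_a - 1) / (n (n - 1))` with missing genotypes excluded
from `n`; for a biallelic site with counts k and n−k this is k(n−k)/C(n,2),
the unbiased estimator of heterozygosity (E = 2p(1−p)). Sites with more than
two alleles use the general sum. Indels are excluded.

Total pi divides the summed per-site values by the number of callable sites,
variant or invariant, where callable means depth >= `min_depth` (5) in at
least `min_presence` (80%) of individuals — the presence fraction mirrors the
dataset-2 rule, since no separate value is published for invariant sites.
The confidence interval is a percentile bootstrap across sites (default
10,000 replicates): the full callable-site list is resampled with invariant
sites contributing zeros, implemented exactly as a multinomial draw over the
variant-site multiplicities. Genotypes at variant sites are depth-masked with
the same minimum before pi is computed, which leaves the estimator unbiased
(masking is independent of allele state).

Calibration: with a single source pool the generator draws each polymorphic
site's alt frequency uniformly on (0,1), so the expected per-site diversity is
`per_site_theta`·E[2p(1−p)] = theta/3. The calibration experiments use
theta = 0.009 (expected pi 0.003) on 20 kb genomes — about 14,000 callable
sites and ~130 segregating sites per replicate. That size is chosen for
statistical sanity: percentile bootstraps are known to undercover when the
effective number of resampled units (here, segregating sites) is small, and
~130 sites puts the interval in its nominal regime.

## Synthetic data: what it emulates, and what it does not

Emulated: planted EcoRI sites at ~1.5 kb spacing (accidental occurrences are
destroyed first, so locus truth is exact); per-molecule insert lengths from
Normal(600, 100) truncated to [read_length/2, 2·mean], which reproduces the
read-through geometry without modelling sonication physics; adapter sequence
(Illumina TruSeq read-through by default) beginning exactly at the insert
boundary; uniform per-base substitution error; diploid individuals drawn from
one or more source pools, with per-pool allele frequencies Beta-distributed
around a shared ancestral frequency so pools are differentiated;
microsatellites of di- to hexanucleotide motifs with per-haplotype unit
counts, with downstream coordinates shifted consistently through an offset
map; Poisson read depth per haplotype and a Poisson per-site depth table
standing in for the mapping stage.

Not emulated: indels (outside SSR length variation), quality-score error
profiles (qualities are constant; errors are uniform substitutions), PCR
duplicates, allele dropout at restriction sites, paralogy beyond what the
repeat-removal rule sees, and reference mapping itself — the variant-calling
stage is pluggable, and synthetic runs consume the generator's truth VCF and
depth table. Passing tests therefore demonstrate the correctness of the
implemented algorithms under the stated error model, not robustness to
mapping artefacts or non-uniform error structure in real libraries.

## SSR scanning and genotyping

The scanner finds maximal period-m regions (2 <= m <= 6) with a vectorised
`s[i] == s[i−m]` comparison; N breaks runs. Only whole units are reported.
Each region yields one candidate per *left-maximal phase* — when an adjacent
locus of a different period claims a run's first bases, a start re-phased
inside the first unit can still be a maximal perfect run — and overlaps are
resolved longest-first (ties: leftmost, then shortest motif), so reported loci
never overlap. Motifs must be primitive; classes are canonicalised as the
lexicographic minimum over all rotations of the motif and its reverse
complement (dimer classes are exactly AC, AG, AT, CG; trimers form 10
classes). Unit minima default to 5/4/4/4/4 for di- through hexanucleotides,
the inclusive reading of the screening rule; a strict reading (>= 6 dimers) is
available by passing a different minima map.

Genotyping is a simplified spanning-read caller: a read (either orientation)
is informative when it contains `min_border` (5) exactly matching flank bases
on each side of a perfect repeat of the locus class; the allele is the
spanned length in bp. Ambiguous reads (multiple inconsistent spans) are
discarded. Per individual, the two best-supported lengths are called, the
second requiring at least 2 reads and a quarter of the first's support. The
locus quality is `10 · sum_individuals log2(1 + support)` — a support-based
plumbing score on its own scale, deliberately not comparable to any external
genotyper's likelihood-based quality; the 300 threshold is applied to it only
in self-consistent synthetic screening.

## Primer design and e-PCR

Melting temperature uses the GC rule `64.9 + 41·(GC − 16.4)/L` — simple and
deterministic; absolute values differ from thermodynamic nearest-neighbour
models, so the 55–65 °C constraint selects on this model's scale, not a
calibrated one. Candidates are enumerated exhaustively over all windows of
length 18–24 in 200 bp of each flank, filtered on Tm, GC 40–60%, absence of N
(variant positions are masked first) and product size 125–250 bp containing
the repeat, and ranked by distance from the optima (21 nt, 60 °C, 50%).

Electronic PCR anchors candidate sites at exact matches of the primer's last
three 3' bases (3'-terminal mispriming does not amplify), then aligns the
remainder. The mismatch/gap budgets (2 and 2 per primer) apply to the
*minimal* edit script at a site: among all alignments, only those with the
fewest total edits are considered, and the site binds iff one of them fits
both per-type budgets. Gaps within one alignment must lie on one side (a net
indel in the priming duplex) and the 5'-terminal base must pair. These three
rules together make the budget semantics sharp: a site differing by three
substitutions can never be rescued by a costlier gapped alignment, matching
how bitap-style error counting behaves in established e-PCR tools. Products
form between a plus-strand and a downstream minus-strand site of the pair
within a size window (design range ± 50 bp by default); pairs with exactly
one product across the full contig set are retained.

## Determinism and problem sizes

Every stochastic component draws from `numpy` generators seeded from a single
run seed (per-stage seed sequences), tie-breaks are lexicographic, and gzip
output zeroes the embedded mtime, so reruns are byte-identical. The bundled
experiments use desk-scale sizes chosen to exercise every code path with
comfortable statistical resolution: 1,000-pair trimming experiments, a
100-locus genome for catalog recovery, 200 replicate datasets (1,000
bootstrap replicates each) for CI calibration, 2,000–10,000 random kilobase
sequences for scanner/oracle agreement, and a 50-contig set for e-PCR
validation.

## Known limitations

* The clustering stage has no gapped matching and no SNP-model error
  correction; loci whose alleles differ by indels within the first 85 bp will
  split.
* The reverse-contig assembler assumes substitution-only errors; indel errors
  would shift layout columns.
* The merge splice resolves overlap conflicts whole-sided (by support), not
  column-wise.
* The invariant-site depth table is an input contract; when it comes from a
  real mapping stage its biases (mappability, duplicates) propagate directly
  into the pi denominator.
* The Tm model and the SSR genotype quality are internal scales; thresholds
  on them are screening devices, not physical calibrations.
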