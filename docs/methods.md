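# Methods

`clonescan` detects and calibrates signatures of recombination and
inter-individual genetic exchange in diploid populations that may reproduce
partly or wholly clonally. This note records the models, the estimators'
conventions, the simulation designs behind the calibration experiments, and
the numerical and design choices that were genuinely open.

## The forward model (`simpop`)

A constant-size Wright–Fisher population of `Ne` diploids. Each offspring
is, independently, **clonal** with probability `c` (a mitotic copy of one
fitness-weighted parent) or **sexual** (two fitness-weighted parents, one
recombinant gamete each, crossovers Poisson at rate `r` per bp). Parent
sampling is multinomial with replacement, proportional to fitness; selfing
is allowed. New mutations arise at `mu` per bp per transmitted genome copy.
A fraction 0.4/1.4 of mutations is deleterious with gamma-distributed
selection coefficients (mean −0.01, shape 0.1) and additive within-locus
dominance (heterozygote `s/2`, homozygote `s`), multiplicative across loci.
Two site models: *infinite sites* (each mutation opens a biallelic site at a
fresh continuous coordinate) and *finite4* (Jukes–Cantor mutation among 4
alleles at integer coordinates; this produces recurrent mutation and
triallelic sites). Within-locus **gene conversion** acts per segregating
site per individual per generation at rate `alpha`: a heterozygous site is
overwritten by one haplotype's allele, donor chosen with probability 1/2 —
conversion erodes heterozygosity but conserves expected allele frequencies.
Conversion tracts have length one site by design; tract-length models are
out of scope.

Fitness bookkeeping attaches one selection coefficient per site, carried by
the most recent selected mutant allele at that site; under finite4 a later
mutation at the same site replaces the site's effect. Coordinates are striped
over `n_contigs` equal-length contigs at export; physical distance is only
defined within a contig.

Two initial conditions are available: `monomorphic` (all-identical
population, the classic burn-in design) and `equilibrium`, which seeds the
population from neutral mutation–drift equilibrium using a built-in Kingman
coalescent (pairwise coalescence rate 1/(2Ne) per generation, mutations
Poisson on branches). Independent genealogies are drawn per linkage window
of width ~1/(4Ne·r) — the scale beyond which equilibrium LD has decayed —
capped at one window per contig when crossover is absent, so the starting
state approximates the linkage structure of a long-run recombining
population rather than leaving whole contigs perfectly correlated (which
would inflate the between-replicate variance of mean F_IS several-fold).
The initializer is validated against coalescent theory
(E[S] = θ·a_{n−1}, pairwise diversity θ = 4Ne·mu) and against msprime as an
independent oracle in the test suite.

### Presets

* `PAPER_PRESET`: Ne = 2500, L = 10⁶ bp, mu = r = 10⁻⁶ per bp per
  generation (4Ne·mu = 4Ne·r = 0.01), 200,000 generations from a
  monomorphic start. This is the full-scale design; it is provided for
  completeness and not exercised by the test suite.
* `SCALED_PRESET` (desk scale): Ne = 1500, L = 10 kb,
  mu = r = 0.01/(4·Ne) per bp (so 4Ne·mu = 4Ne·r = 0.01, matching the
  full-scale preset), 2Ne = 3000 generations from a neutral sexual-equilibrium start.
  The quantity that separates the cloning-rate regimes is the
  population-scaled rate of sex Ne·(1−c) — the mean F_IS deviation under
  rare sex scales like −1/(2·Ne·(1−c)) — so Ne is kept large enough that
  cloning rate 0.99 stays deep in the sexual-like regime
  (Ne·(1−c) = 15) while 0.999 sits clearly on the clonal side
  (Ne·(1−c) = 1.5); a much larger Ne narrows the gap between the 0.999
  regime and the fully sexual baseline's sampling spread at desk-scale
  genome lengths, and a much smaller one drags 0.99 toward
  distinguishability. The 2Ne run covers the identity-disequilibrium
  timescale 1/(1−c) for every rate on the grid and, with the equilibrated
  start, the clonal lineage-sorting timescale for the strictly clonal
  case.

## F_IS and the clonality calibration (`genostats`)

Per-site F_IS = 1 − Ho/He, with Ho the observed heterozygote count and
He = 2p(1−p)n **rounded to the nearest integer**. The rounding tie rule is
round-half-to-even by default (configurable to half-up); sites whose He
rounds to zero are flagged undefined and excluded from means. F_IS is 0 at
Hardy–Weinberg proportions, −1 when all individuals are heterozygous, +1
when heterozygotes are absent. Note that this estimator — 8 individuals,
minor-allele-count filter ≥ 4, integer-rounded He — carries a small
negative bias (≈ −0.05) even for a perfectly random-mating population; all
comparisons in the calibration are therefore simulation-vs-simulation under
the identical estimator, and the bias cancels.

The cloning-rate sweep runs `SCALED_PRESET` at cloning rates
{0, 0.5, 0.9, 0.99, 0.999, 1.0}, 20 replicates each; per replicate, 8
individuals are sampled, biallelic SNPs with MAC ≥ 4 kept, 200 SNPs drawn
(all qualifying SNPs when fewer are available — the 10 kb genome typically
yields 100–200 qualifying SNPs) and their mean F_IS recorded. Because
clonality depresses F_IS and never raises it, the comparison is one-sided:
a cloning rate is *indistinguishable from fully sexual* when the median of
its replicate means does not fall below the lower bound of the central 95%
interval of the cloning-rate-0 means. The sweep's summary quantity is the
smallest sexual-reproduction rate (percent) that is indistinguishable while
all rarer-sex regimes fall below the bound.

The one-sided clonality p-value for observed data is the fraction of
simulated SNP-set means at least as large as the minimum observed set mean,
exactly as defined for that comparison — deliberately without the
add-one convention used elsewhere, and without multiple-comparison
correction.

Triallelic analysis: with N2 biallelic and N3 triallelic sites,
P3 = N3/(N2+N3) estimates the per-site probability of a second mutation, so
without genetic exchange the expected number of triallelic sites carrying
all three heterozygote classes is P3·N3; the departure of the observed
proportion is tested by a one-sample Z-test for proportions (no continuity
correction, two-sided). Private-heterozygote carriers (sites whose least
frequent heterozygote class occurs in exactly one individual) are tested
for uniformity across individuals by a chi-square goodness-of-fit — a
descriptive guard against cross-sample contamination, which would
concentrate private heterozygotes in few individuals.

## Clonal Hardy–Weinberg equilibrium under conversion

In a strictly clonal population, within-individual allele pairs coalesce
only through gene conversion (expected time 1/alpha), while chromosomes in
different individuals coalesce through the clonal genealogy (expected time
~2Ne including excursions through the within-individual state). Setting
alpha = 1/(2Ne) equalises the two timescales, so heterozygosity matches the
Hardy–Weinberg expectation despite strict clonality; deviations of alpha in
either direction push F_IS negative (slower conversion, heterozygote
excess) or positive (faster conversion, heterozygote deficit). The
experiment (`clonal_hwe_experiment`) verifies the equilibrium point and
both directions at alpha ∈ {0.1, 1, 10}/(2Ne).

Design choices: the experiment runs **neutrally** (deleterious fraction 0),
because the balance argument concerns the neutral coalescent — with a
deleterious load, clonal background selection shortens the
between-individual timescale (Ne_eff < Ne) and shifts the equilibrium away
from 1/(2Ne), which is a statement about selection, not about the
conversion balance being tested. Ne is small (150) because the shape of an
8-individual sampled genealogy — hence the F_IS distribution — is
scale-free in Ne, and the run must cover ≳ 10/alpha generations to reach
conversion–mutation equilibrium.

The readout pools the observed and expected heterozygote counts across the
60 replicates per alpha and takes a single ratio 1 − ΣHo/ΣHe (the
ratio-of-sums construction standard for multi-locus F-statistics). Pooling
matters: the per-replicate F_IS of an 8-individual sample fluctuates with a
standard deviation of ≈ 0.4 under clonal genealogies (the whole sample
often descends from one or two recent clonal lineages), and averaging
per-replicate *ratios* then carries a Jensen-type bias of −0.1 to −0.2 even
when the population is exactly at the Hardy–Weinberg point. We verified
directly that the state process sits at the predicted equilibrium — the
within-individual per-bp heterozygosity matches 2μ/(2μ + α) and the
within/between ratio is 1 at α = 1/(2Ne) — while the mean of per-replicate
ratios stays ≈ −0.2; the pooled ratio correctly returns ≈ 0. The per-site
mean-of-ratios estimator is retained, unchanged, in the cloning-rate sweep,
where all comparisons are simulation-versus-simulation under the identical
estimator and its bias cancels.

## LD statistics and per-segment tests (`ldstats`)

r² between phased biallelic sites is D²/(pA qA pB qB), equal to the squared
Pearson correlation of allele indicators; the unphased analogue is the
squared Pearson correlation of genotype dosages; the all-homozygous path
builds one pseudo-haplotype per individual from sites homozygous in every
individual. Pairs are filtered at MAC ≥ 4 by default. Distance binning uses
left-closed fixed-width bins (200 bp default, ≤ 4000 bp) or equal-count
bins, with 95% percentile-bootstrap CIs (1000 replicates); cross-contig
pairs provide the no-linkage baseline (mean, median, 10–90th percentiles).
The decay curve is a second-degree LOESS (tricube weights, span 0.4,
written in-house since no installed package provides degree-2 LOESS),
together with the smallest distance at which the smoothed curve enters the
cross-contig baseline mean ± 1 SE band.

Three per-segment recombination tests share a permutation null that
shuffles SNP positions along the segment while holding the haplotype
columns fixed (position permutation chosen over genotype-label permutation;
documented as an open choice):

* **r²–distance**: Pearson correlation of pairwise r² with distance;
  one-sided p = fraction of permutations with correlation ≤ observed.
* **Sum of distances (D4)**: total distance over site pairs displaying all
  four gametes; one-sided p for D4 ≥ observed.
* **PHI** (pairwise homoplasy index): mean incompatibility (all four
  gametes present) over informative-site pairs within a 100 bp window.
  Under recombination nearby pairs are *more* compatible than distant
  ones, so the test is lower-tailed in the permutation distribution;
  without recombination, incompatibility from recurrent mutation carries no
  distance signal and site order is exchangeable. The default is the
  permutation p; a normal approximation using the exact Mantel-type
  permutation mean and variance of the statistic is available (the moment
  formulas are verified against exhaustive enumeration in the tests). The
  window is measured in base pairs of the reconstructed alignment, in which
  non-SNP columns are monomorphic and cannot be informative.

All permutation p-values outside the clonality calibration use the add-one
convention (b+1)/(m+1), so the smallest attainable p is 1/(n_perm+1).
Type-I error and power of the three tests are calibrated on simulated
recombination-free (strictly clonal) versus sexual (4Ne·r = 0.01/bp)
segments at Ne = 100, 200 segments per regime, 199 permutations per test.

## The modified four-gamete test (`fourgamete`)

Within-locus gene conversion turns heterozygous genotypes homozygous but
never the reverse, so it cannot create a pair of individuals each
heterozygous at two sites while jointly carrying all four gametes. The scan
enumerates, per phased segment and per unordered individual pair, all site
pairs heterozygous in both individuals, and flags a pair *recombinant* when
the four phased haplotypes display four distinct gametes. For biallelic
sites each doubly heterozygous individual carries a complementary gamete
pair, so gamete counts are 2 or 4. Records are pooled over individual pairs
by default (a per-site-pair deduplicated mode exists). Equal-count distance
bins (boundary ties to the lower bin) summarise the recombinant fraction
with bootstrap CIs; pairwise bin contrasts and the recombinant versus
non-recombinant mean-distance contrast use 10,000-permutation two-sided
tests. Conversion-proofness is verified by simulation: strictly clonal runs
with conversion and no crossover must produce exactly zero recombinant
pairs under infinite sites; under finite-site recurrent mutation,
recombinant pairs appear but their frequency carries no increasing distance
trend.

## Phasing quality control (`phaseqc`)

Read-based phasing output is modelled as per-individual blocks of
heterozygous SNPs with phred-like switch/mismatch scores. Filters:

1. *Conflicting evidence*: a block is discarded when any of its site pairs
   is covered by fragments supporting more than two distinct two-site
   combinations (each supported by ≥ `min_reads`, default 1; a diploid can
   carry at most two haplotypes over any pair of sites).
2. *Quality split*: blocks with more than one SNP under quality 100 are
   discarded; blocks with exactly one are split at that SNP, which is
   excluded from both halves.
3. *Homozygous complementation*: homozygous SNPs strictly inside a block's
   heterozygous span are assigned to both haplotypes (their phase is
   trivial). Complementation is applied after block filtering.
4. *Common segments*: maximal contig intervals where every requested
   individual is covered by exactly one block; kept when they contain at
   least 15 SNPs (default) whose minor allele occurs in ≥ 2 of the phased
   haplotypes ("non-singleton", defined here since the term is standard but
   unpinned).

All filters are idempotent. Switch inconsistency between two phasings of
one individual is the fraction of adjacent co-phased heterozygous SNP pairs
whose relative phase orientation differs; it is symmetric and invariant
under whole-block haplotype flips.

## Haplotype incongruence and monophyly (`haplophylo`)

Distances between segment haplotypes are SNP-difference (Hamming) counts
over the phased SNP columns (remaining positions monomorphic); the
unambiguity margin is stated in SNPs (default 3: the runner-up counterpart
must be at least 3 SNPs farther than the best). Classification of one
individual's haplotype pair: both haplotypes need unambiguous closest
counterparts in other individuals; both counterpart distances must be
strictly smaller than the within-individual distance (configurations
violating this are reachable by gene conversion and are excluded); matches
must be reciprocal (the focal haplotype is its counterpart's unique best
match). The grouping is *congruent* when both counterparts live in one
individual and *incongruent* otherwise, with the unordered partner pair as
the pattern; anything else is *undetermined*. Strict inequality is used for
both haplotypes in the within-distance rule.

The paralog screen drops a segment when any haplotype has BLAST-style hits
to more than 10 contigs or more than 2 hits with ≥ 90% identity (hit tables
are consumed as TSV; alignment itself is out of scope).

Trees are neighbour-joining (scikit-bio, negative branch lengths clamped to
zero) on the SNP-difference matrix, with supports as the percentage of SNP
column-bootstrap replicates containing each bipartition, and midpoint
rooting (supports re-attached by bipartition identity). Externally inferred
newick trees (e.g. maximum likelihood) are ingested through the same
interface, with numeric internal labels read as supports. The monophyly
scan reports maximal clades composed exclusively of target haplotypes with
support ≥ 70%, their sizes, whether they hold exactly one haplotype per
target individual, and whether the root bipartition separates them.

## Hybrid-origin experiment

`simulate_hybrid_scenario` evolves two populations from a common
equilibrated ancestor for 1600 generations (20 Ne at the hybrid preset's
Ne = 80) and forms F1 individuals with one recombinant gamete from each.
The recovery experiment samples 3 hybrids plus 8 individuals from
population A only — mirroring a design in which the second parental
population is unsampled — and checks that (i) among informative segments
(those where the counterpart classification is determined) the two
haplotypes of each hybrid find reciprocal counterparts tracing to different
source populations, and (ii) the monophyly scan finds well-supported clades
holding exactly one haplotype per hybrid (the unsampled-population side)
but never a clade of all hybrid haplotypes. The hybrid preset's mutation
rate (10⁻⁴/bp) is set so that within-population nearest-neighbour distances
on 1 kb segments exceed the 3-SNP margin; at low diversity the
counterpart procedure is (correctly) undetermined almost everywhere.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the methods consume:
diploid genotypes and truth haplotypes under tunable clonality, conversion,
crossover, selection and recurrent mutation, multi-contig coordinates, and
phased-block/fragment artefacts assembled from truth. It does not emulate
sequencing error, coverage variation, index hopping, reference bias,
repetitive-region artefacts, or real phasing errors (switch errors can be
injected only by construction in tests). Passing calibrations therefore
demonstrate correctness and statistical behaviour of the estimators on
clean genotypes, not robustness to upstream calling artefacts — the
filtering steps (`phaseqc`, paralog screen, MAC filters) implement the
guards a real-data analysis needs for those, but their effectiveness on real reads is
not testable here.

## Numerical choices

* Permutation p-values: add-one convention; ties counted as at least as
  extreme (with a 10⁻¹² slack on float comparisons).
* He rounding: banker's rounding by default; the tie rule is configurable
  because the original description ("nearest integer") does not pin it.
* Bootstrap CIs: percentile method.
* NJ negative branch lengths are clamped to zero; midpoint rooting on an
  all-zero-length tree roots arbitrarily and flags the tree.
* The simulator prunes fixed columns every 10 generations and keeps
  columns position-sorted; fitness is recomputed each generation from the
  selected columns only. A numba compiled path accelerates the offspring
  copy, crossover splicing and fitness loops, with numpy fallbacks that are
  verified equivalent in the tests.
* Problem sizes for the calibration experiments (replicate counts,
  permutation counts, bootstrap counts, segment counts) are chosen so each
  experiment resolves its target contrast with comfortable Monte-Carlo
  margins; they are recorded in `clonescan.calibration` as the presets.
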