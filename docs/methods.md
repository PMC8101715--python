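# Methods

This note documents the statistical procedures implemented in `herdgen`,
the defaults chosen where the literature leaves room, and what the
simulation-based tests do and do not demonstrate.

## Pedigree inbreeding and derived parameters

**F (Meuwissen–Luo).**  For an individual with parents *s* and *d*,
1 + F equals Σ L_j² D_j over the ancestors *j* of the virtual s×d
offspring, where L_j is the expected genetic contribution of *j* and
D_j = 1/2 − (F_sire(j) + F_dam(j))/4 is the Mendelian sampling variance
(unknown parents enter as unrelated, non-inbred founders, giving D = 1
for founders and D = 3/4 − F_known/4 for half-known parentage).  The
ancestor walk processes youngest-first so each ancestor is expanded once.
Individuals with any unknown parent get F = 0 — the convention of
pedigree software for livestock, where missing parentage is treated as
outbred.  Equivalence with Wright's path-counting coefficient is enforced
by test on random pedigrees (tolerance 1e−12).

**CGE.**  Complete generation equivalents are computed by the recursion
CGE(i) = Σ_parents (1 + CGE(p))/2, equal to summing (1/2)^g over all
known ancestor slots.  Founders have CGE 0.

**Completeness.**  Per parental generation *d* the proportion of the 2^d
ancestor slots filled is reported.  The summary index is the harmonic
mean of the paternal- and maternal-line completeness (each line's mean
filled proportion over generations 1..depth), 0 when either line is
unrecorded.  The precise index variant used by classic pedigree programs
is not fully published; the harmonic-mean form implemented here is the
documented one and is flagged as an assumption.

**Generation intervals.**  A parent–offspring pair contributes only when
the offspring itself has recorded progeny ("kept for reproduction",
operationalised as ≥1 offspring in this pedigree).  Pairs missing a birth
year on either side are dropped and counted.  Intervals are reported per
gametic pathway (sire→son, sire→daughter, dam→son, dam→daughter) and
overall.

**ΔF and Ne.**  ΔF is the OLS slope (with intercept) of individual F on
individual CGE; regressing on CGE rather than birth year makes the rate
per *generation equivalent* and robust to uneven pedigree depth.
Subpopulation mode applies ΔF = b / (1 − (F̄ − b)).  Ne = 1/(2ΔF);
non-positive ΔF yields an infinite Ne with a warning rather than a
negative number.  For ROH-based Ne the absolute slope is used to avoid
negative effective sizes.  Individuals with F = CGE = 0 are retained in
the regression by default.

**f_e and f_a.**  Founder contributions q_k follow the deterministic
half-from-each-parent gene-flow recursion, with unknown-parent slots
absorbing their half of an individual's genome (the individual acts as
founder for that fraction); Σq_k = 1 is asserted.  f_e = 1/Σq_k².  The
effective number of ancestors uses the greedy marginal-contribution
algorithm: each round scores every candidate by (genes reaching it that
no previously chosen ancestor already explains) — implemented as the
arrival weight with flow absorbed at chosen ancestors, multiplied by the
probability that the candidate's own genome escapes the chosen set when
traced upward — picks the maximum, and stops when the residual falls
below 1e−9.  This reproduces f_a = f_e on bottleneck-free pedigrees and
f_a < f_e when a non-founder funnels founder genes.

## ROH detection and ROH inbreeding

Detection follows the sliding-window procedure standard for SNP-chip
data.  Defaults: 50-SNP window, ≤1 heterozygous and ≤2 missing calls per
homozygous window, SNP hit rate > 0.05 to join a run, runs split at
inter-SNP gaps > 1 Mb, accepted runs need ≥100 SNPs, ≥1 Mb, and ≤100 kb
per SNP.  The window-hit threshold and minimum-run settings are the
de-facto tool defaults; they are configurable and flagged as assumptions
because published studies often omit them.  Segment length is
end − start + 1 bp of the bounding SNPs, with no extrapolation beyond
genotyped positions, consistent with defining L_AUTO from SNP coverage.
Missing calls inside an accepted run count toward its length but not its
SNP tally.  Chromosomes shorter than the window are scanned with a
truncated window and logged.

A boundary consequence of the hit-rate rule worth knowing: the outermost
SNPs of a long homozygous run lie mostly in windows that extend into the
flanking heterozygous background, so a run's accepted extent is a few
SNPs narrower than the homozygous stretch itself.  The naive quadratic
oracle in the test suite implements the same rules independently and
agrees exactly.

F_ROH_L divides total ROH length by L_AUTO (sum over chromosomes of
last-SNP − first-SNP + 1); F_ROH_N divides SNPs-in-ROH by N_SNP.  Both
denominators are always recomputed from the loaded map, never hard-coded.
The chromosomal measures F_ROH_KK (per-chromosome coverage denominator)
and F_ROH_KA (autosomal denominator) partition total inbreeding;
Σ_k F_ROH_KA = F_ROH_L holds exactly and is asserted at 1e−15 in the
pipeline's self-checks.  Chromosome rankings (ties broken by ascending
chromosome number) and the cumulative percentage of inbreeding burden are
reported for both measures.

## QC and heterozygosity

Filter order: individual call rate → SNP call rate → MAF → HWE.  The
order follows conventional tool behaviour; thresholds are inclusive
(≥0.90 call rate and ≥0.05 MAF kept).  The Hardy–Weinberg test is the
exact conditional test on genotype counts (two-sided, summing
probabilities ≤ that of the observed table; mid-p available but off),
chosen over the chi-square because cohorts of interest are small
(tens of individuals).  LD pruning removes, within each sliding window,
the SNP with the largest variance-inflation factor until all VIFs are
below threshold (VIF 2 ⇔ multiple R² ≤ 0.5); singular windows drop the
later SNP.  H_o is each individual's heterozygous fraction of non-missing
calls; H_e is the SNP-mean of 2p(1−p) with the small-sample factor
2n/(2n−1) on by default and the uncorrected value also reported, since
published H_e values rarely state the variant.

## LD-decay effective population size

Composite r² (squared Pearson correlation of unphased dosages,
pairwise-complete individuals) is computed for intra-chromosomal pairs up
to 10 Mb apart.  Pairs are binned into 30 equal-width distance bins; each
bin's mean distance maps to a recombination rate by the linear rule
1 Mb = 1 cM (capped at 0.5 Morgan), chosen as default because it makes
the 10 Mb cap correspond exactly to t = 1/(2c) = 5 generations ago — the
"most recent" estimate convention; a Haldane mapping is available.  The
sample-size adjustment subtracts 1/n with n = 2 × individuals (haploid
count, configurable to diploid).  The estimator is
N(t) = (4c)⁻¹ (E[r²_adj]⁻¹ − α) with the mutation correction α = 1 (none)
by default, options 2 and 2.2.  Bins with fewer than 50 pairs are
dropped; bins implying non-positive Ne are kept but flagged invalid.

## Synthetic cohorts

The generator provides the study conditions for all tests: a
26-autosome map with SNP counts proportional to chromosome rank (total
40,753, ~66 kb even spacing, ~2.6 Gb coverage — the geometry of a
medium-density ovine chip after QC), founder allele frequencies uniform
on [0.05, 0.5] (a post-QC-like spectrum so the MAF filter removes almost
nothing), and Poisson crossovers at 1 cM/Mb with uniform placement and no
interference — deliberately the same map function the Ne estimator
assumes, so simulator and estimator are mutually consistent.

The default pedigree is 12 founders and three non-overlapping-by-litter
generations of 46 offspring with random within-flock mating; drift in so
small a founder pool produces related matings and a cohort whose mean
F_ROH_L (~4%) and pedigree–genomic inbreeding correlation (~0.88) sit in
the range reported for small monitored sheep flocks.  Birth years are
base + generation + uniform{0,1,2}, giving the overlap the
generation-interval code must handle.  `record_loss` erases parent links
(observed pedigree only; gene dropping always uses the complete truth)
to create the CGE gradient the ΔF regressions need.  Bottleneck mating
(all matings through k sires) produces f_a < f_e by construction.  All
draws descend from the single mandatory seed.

Truth output records IBD segments (both inherited haplotypes carrying the
same founder-haplotype label) and the per-individual IBD fraction of map
coverage; tests verify Mendelian consistency, E[IBD] = 0.25 for
parent–offspring matings, regression of realised IBD on F_PED near 1, and
≥80% recovery of true IBD segments longer than 2 Mb by the ROH detector
on a dense (10 kb) map.

**What the simulator does not emulate:** mutation, selection, migration,
genotyping error, realistic ovine recombination maps (hot/cold spots,
sex differences), and chip ascertainment bias.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to these real-data features; in particular H_o/H_e and LD
levels in real chip data reflect ascertainment the simulator does not
reproduce.

## Problem sizes used in validation

The test and acceptance workloads are sized for quick desk-scale runs,
as the package's own choice of validation scale: the headline cohort is
46 individuals × 40,753 SNPs; inbreeding-rate recovery uses 20 replicate
pedigrees of 30 animals × 10 generations against the theoretical
ΔF = 1/(2N); LD-Ne recovery uses 10 replicates of a constant-size N = 100
population run for 60 generations on a 6-chromosome, 4,200-SNP map
(recent bins, t ≤ 10, recover N within a factor of 2); oracle
equivalence runs 50 random pedigrees, 100 random chromosomes and ~40
genotype tables.

## Known limitations

- The exact-HWE and VIF-pruning procedures mirror the conventional tools
  in behaviour but not necessarily in every tie-break; pruning keeps the
  earlier SNP on ties, which can differ from other implementations.
- f_a's greedy algorithm is order-dependent by construction (as in the
  original); contributions are deterministic given the pedigree but not
  unique across tie permutations.
- LD-based Ne inherits the usual caveats of the r²-decay method: bins at
  large t mix epochs, and the sample-size and mutation corrections are
  approximations; confidence intervals are not provided.
- PLINK file support covers the v1.0 SNP-major binary and text formats;
  VCF, phased data and sex chromosomes are out of scope.
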