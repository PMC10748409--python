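# Methods

This note documents the models, conventions and numerical choices
behind panelforge, and what the synthetic data does and does not
emulate.

## Coordinates and formats

Intervals are 0-based half-open internally; every user-facing table is
1-based. Chain files use the UCSC dialect (source strand always `+`;
minus-strand destination coordinates counted on the reverse
complement), with the score field set to the aligned block length.
FASTA is written at 60 columns. Genotypes are encoded 0/1/2 as the
count of alternate alleles and emitted unphased (PED/MAP text and
VCF v4.2); phase exists only inside the generator's truth set.

## Liftover and conservation

A SNP's window is `2*flank` bases with the SNP at offset `flank`
(default 50: a 100-bp window with 50 bases left and 49 right of the
SNP). Lifting maps every base through the ungapped blocks of the single
best-scoring overlapping chain; the lifted interval is the forward-
strand envelope of the mapped positions. A window fails as unmappable
when the mapped fraction is below `min_mapped_fraction` (default 0.95,
the usual region-level liftOver default; bases reachable only through
other chains do not count, so windows split across chains or strands
fail). Orthologs longer than 1,000 bp and placements on contigs whose
name starts with `chrUn` (configurable) are excluded next.

Conservation is judged on a *pairwise* global alignment of the source
window against the lifted target sequence (match +1, mismatch −1,
linear gap −2, via biopython's PairwiseAligner): the SNP is conserved
iff the alignment column containing the SNP base is not a gap in the
target row. Only the target-row gap decides the call, so additional
species in a multiple alignment would not change the decision rule;
they are deliberately out of scope.

## Annotation-based prioritization

Sub-gene features of ≤ 50 bp are removed before any overlap
computation (the filter direction is configurable; removing them is the
reading under which the step has an effect). A locus "overlaps a UTR"
when it touches an annotated UTR of a gene and that gene's coding
exons (union over transcripts) cover strictly less than two thirds of
the locus length. Nearest-TSS queries split candidates at the locus
midpoint (upstream: TSS ≤ midpoint; downstream: TSS ≥ midpoint),
measure distance to the interval itself (0 when the TSS falls inside),
and break ties toward the lexicographically smaller gene id. Hubs are
genes with strictly more than 10 distinct interaction partners over
edges with curated-evidence score strictly above 0.5. The DEG list is
consumed as a plain gene-id list; the differential-expression
thresholds that produced it are the provenance contract of that input
and are not recomputed here.

## Haplotype blocks and proxies

Two-locus haplotype frequencies come from the standard EM for unphased
genotypes (uniform start, convergence at 1e-9, 1,000 iteration cap;
only double heterozygotes are phase-ambiguous). D′ confidence
intervals follow the Gabriel/Haploview construction: allele frequencies
fixed at their sample estimates, sign of D absorbed by allele
relabelling, likelihood evaluated on a |D′| grid of step 0.001, CI
bounds at the 5th/95th percentiles of the normalized cumulative
likelihood; the reported point estimate is the grid maximum (clamped
into the CI, so estimate ∈ [CI_low, CI_high] holds by construction).
Block criteria use the Haploview defaults that PLINK `--blocks`
adopts — strong LD: CI_low ≥ 0.70 and CI_high ≥ 0.98; strong
recombination: CI_high < 0.90; informative fraction 0.95; maximum span
200 kb — all exposed as parameters. Candidate blocks are ranked by bp
span and accepted greedily without marker overlap. The phenotype
restriction some genotype tools apply has no analog here (no phenotype
accompanies the panel); it is a documented no-op.

The median block span is computed over all detected blocks of the
analyzed panel. Proxy assignment takes each prioritized locus to its
nearest known SNP (distance to the interval, ties to the lower
coordinate); loci sharing a proxy are merged so each proxy appears
once, and a locus is "within the median block" when its distance is
strictly below the median span.

## Consensus genotyping

Normalization is the standard left-align/parsimony algorithm (trim a
shared trailing base; left-extend with the preceding reference base
whenever an allele empties; finally trim shared leading bases); it is
checked in the tests against both an exhaustive left-shift oracle and
`bcftools norm`. Calls are matched on chrom+pos+ref+alt after
normalization, SNPs and indels alike. A per-sample consensus call
requires presence with QUAL ≥ 20 in all three callers; the pooled set
is the union of consensus calls over samples.

For a pooled variant, a sample with no call from any caller is
homozygous reference. A sample where only one or two callers called is
governed by `carrier_rule`: the default `strict` marks it missing
(which then fails the cohort filter's "everyone else homozygous
reference" requirement); `any_caller` implements the literal reading
that only sites called by no caller are reference — any call implies a
carrier, with the callers' majority genotype. When three callers
disagree on genotype the 2-vs-1 majority wins, else heterozygous.
Cohort polymorphism keeps variants with 11–18 carriers (both bounds
configurable; a published variant of the band extends to 19) and no
missing genotypes among the rest. Pattern deduplication groups
variants on the same target with identical per-sample genotype vectors
and keeps the smallest coordinate.

## Survival modeling

The Cox partial likelihood uses the Efron tie correction and is
maximized by Newton's method with step halving (convergence 1e-9,
50 iterations, |β| > 15 or a singular information matrix flags the fit
as non-converged/monotone and excludes it from selection). Wald tests
and AIC = −2 log L + 2k are computed from the observed information.
The solver is intentionally small and fast (~4 ms for n = 300, p = 10)
because the staged selection performs thousands of fits in the
simulation studies; it is validated against lifelines at 1e-6
tolerance, and lifelines provides the Kaplan–Meier estimator.

The staged selection runs exactly: univariable screen keeping p ≤ 0.5;
joint fit of the pool with backward elimination accepting the removal
that most lowers AIC until none lowers it; keep p ≤ 0.1; forward
selection over the screened pool adding the largest AIC decrease while
one exists; keep p ≤ 0.1; bidirectional refinement (best single add or
drop by AIC); variables at p ≤ 0.05 in the final model are reported
significant. Candidates are processed in sorted order and AIC ties
resolve to the first candidate, so the outcome is independent of input
order. An empty pool at any stage returns an empty-model result.

Variants enter the model as binary carrier indicators (0 vs ≥ 1
alternate allele), matching the carrier-based cohort filter; additive
0/1/2 coding is available. Clinical covariates are screened in separate
univariable fits (categorical covariates dummy-encoded; age encoded
adult = 2–7 years → 1, senior → 0) rather than entering the variant
selection, with an option to include them. Risk stratification splits
at the median linear predictor with ties to the low group and reports
each group's Kaplan–Meier median (absent when survival never falls to
0.5). With distinct risk scores the groups differ in size by at most
one; heavily tied scores can make the split uneven, and identical
scores degenerate to a single flagged group.

A known property of the staged procedure, confirmed by the package's
own simulations: with 10 independent null candidates the final
significant set is empty in only ~55–60% of runs (≈ 0.95¹⁰ before
selection effects), because any candidate reaching p ≤ 0.05 necessarily
survives every earlier stage. Stepwise selection does not control the
family-wise error rate; the final p ≤ 0.05 call is per-variable.

## Synthetic data: what it emulates, and what it does not

The generators are deterministic given (seed, config) — identical
seeds give byte-identical output files — and every bundle carries a
`truth.json`.

*Genome pairs.* Each SNP owns a 300-bp region; the planted class
decides its fate (copied, dropped, stretched by a 901-bp insertion
inside the SNP window, moved to a `chrUn` contig, inverted, or copied
with the SNP base deleted), and the chain file exactly records the
derivation. The SNP base is kept distinct from its neighbours so a
deletion at the SNP column has a unique optimal alignment. With no
planted edits the chain degenerates to a single identity block. The
accounting fixture composes class counts directly (default 592 inputs:
68 unmappable, 1 over-long, 1 unplaced, 43 gap-at-SNP, leaving 479
conserved, plus 3 target-species literature SNPs), so the cascade's
output sizes are forced by construction.

*LD panels.* Within a block every chromosome copies one of (default) 4
founder haplotypes generated on a perfect phylogeny — each marker
mutates exactly once on the founder tree, so within-block |D′| = 1, the
property the Gabriel criteria detect; between blocks the founder
lineage resamples with the block's recombination probability (default
free recombination). Defaults: 600 subjects (the scale of the genotype
panel the block map is meant for), 5 blocks of 6–10 markers spanning
4–8 kb, 30-kb gaps, founder frequencies uniform in [0.2, 0.8], no
recurrent mutation (a mutation-rate dial exists; raising it erodes the
CI upper bounds and block recovery, which is the realistic failure
mode of sparse panels).

*Caller VCFs.* Three callers drop true calls at `caller_fn_rate`, add
spurious qual-passing SNPs at `caller_fp_rate`, push a fraction of
QUAL values below 20 (`caller_lowqual_rate`), and re-express indels in
right-shifted non-parsimonious form at `indel_jitter_rate` (indels are
planted in homopolymer runs so a shifted form exists). The cohort
fixture used for the worked-example counts sets FN = FP = 0 with
jitter 0.3, so the consensus counts are forced while normalization is
still exercised; the error rates are exercised by the oracle tests.

*Survival.* Event times follow a proportional-hazards model with
exponential baseline (Weibull shape available), baseline hazard
1/300 per day (median ≈ 208 days, the scale of relapse times in the
motivating cohort), planted log-hazards on designated variants, and
independent exponential censoring whose rate is calibrated by
bisection to the target censored fraction (default 7/29, the
lost-to-follow-up fraction of the motivating 29-dog cohort).

Not emulated: read-level sequencing (FASTQ, coverage, error models),
population structure and relatedness, linkage between the panel's
variants and the survival outcome beyond the planted effects, and real
annotation complexity (overlapping genes, alternative TSS clusters).
Passing tests therefore demonstrate correctness of the algorithms
under the stated statistical assumptions, not robustness to artifacts
of real sequencing data.

## Problem sizes

The test suite and acceptance script run the block-recovery study at
n = 600 subjects over 10–20 seeds, the selection-recovery study at
n = 300 over 20–50 seeds, the null calibration at 500 replicates of
n = 100, and the D′ archetypes at n = 200 over 100 replicates; the full
suite completes in well under a minute per study on one CPU.
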