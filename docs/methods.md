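# Methods

## Measurement model

The assay multiplex-amplifies three short regions from bisulfite-
converted plasma DNA and sequences them to high depth in 150 bp
paired-end mode. The package models that chain generatively and then
analyzes its own output with the same contracts a real pipeline would
use, so the simulator truth table gives an exact oracle for the
analysis stages.

**Panel.** Reference amplicons are synthetic: random DNA in which CG
dinucleotides occur only at designed CpG sites (six per 220 bp region
by default), so `cpg_positions` provably enumerates every CpG. Panels
round-trip through FASTA + BED (0-based half-open), and a real panel
can be substituted file-for-file. Only the original-top (C2T) strand is
simulated by default; G2A is supported symmetrically in the aligner and
caller.

**Fragments and chemistry.** Each on-target fragment is tumor-derived
with probability θ (the circulating tumor fraction). CpG methylation
states are per-fragment Bernoulli draws: probability `m_t` (default 1.0)
for tumor fragments and `m_b` (default 0.01) for background, except
that a background fragment is, with probability ε (the *epimutation
rate*, default 0 in `ReadSimParams`), a coordinately fully methylated
normal allele. ε is what gives control samples their low nonzero
fully-methylated-read percentages; without it the background rate of
fully methylated reads would be m_b^k ≈ 10⁻¹², which is not what
control plasma looks like. Bisulfite conversion sends unmethylated C to
T with probability `c` (0.995) and methylated C to T (over-conversion)
with probability `o` (0.005); non-CpG cytosines are always treated as
unmethylated. Sequencing error is uniform substitution (0.001/base).
Read 1 is the fragment 5′ end, read 2 the reverse complement of the 3′
end; off-target genomic-DNA pairs are drawn from a long random fragment
so the mates never overlap.

**Genomic DNA contamination.** A subject's contamination g (gDNA:cfDNA
mass ratio) couples to reads two ways: off-target pairs make up
g/(1+g) of output (capped at 0.95), driving the mapping-rate QC, and —
because leukocyte genomic DNA amplifies at the target loci but is
unmethylated there — both the tumor fraction and the background
epimutation rate seen by the read simulator are diluted to θ/(1+g) and
ε/(1+g). This one mechanism produces the qualitative behaviour the
stratified analysis looks for: sensitivity falls with contamination,
specificity does not.

**Fragment-size profiles.** The electropherogram stand-in is a binned
mixture of a truncated Gaussian at the mononucleosome mode (167 ± 20 bp,
unit mass, window 50–700 bp) and a high-molecular-weight component
(850 ± 60 bp, mass g, window > 700 bp), built by CDF integration so the
cfDNA/gDNA window ratio equals 1/g exactly up to binning. Profiles are
deterministic; a seeded multiplicative jitter is available but off by
default.

## Analysis contracts

**Alignment.** Amplicon panels make genome-scale gapped alignment
unnecessary, so the aligner is exhaustive and ungapped: mates are
merged (higher base quality wins at overlap disagreements, quality ties
become N; pairs without an acceptable overlap are concatenated as two
sub-reads of one fragment), fragment and references are folded to the
three-letter bisulfite alphabet per region (C2T or G2A), and the best
(region, offset) minimizes mismatches over non-N positions, ties to the
lower region index then lower offset. A fragment maps if its best
mismatch rate is ≤ 10% (configurable). A pure-Python brute-force scorer
over every region × offset is kept in the package as the correctness
oracle and the two are asserted equal on simulated read sets.

**Methylation calling.** At each region CpG covered by the aligned
span, C (top strand) means methylated, T unmethylated, anything else
ambiguous. A read is *fully methylated* only if it covers **all**
region CpGs and every one reads methylated; ambiguous never counts as
methylated. Partially covering reads stay in the denominator (flagged),
since the assay provides no basis for dropping them and the published
pipeline applied no read filtering beyond the sample-level 2%
mapping-rate rule, which is kept with the boundary convention that
exactly 2% passes. Zero mapped reads in a region is reported as
"no amplification" (undefined percentage), never as 0%.

**Threshold calibration and scoring.** Candidate cutoffs are the sorted
unique observed values; positivity is *strictly above* the cutoff, so
control specificity at any cutoff is k/n_controls. The chosen cutoff
minimizes |specificity − target| (target 0.97), ties toward higher
specificity, then toward the lower cutoff — observed values rather than
midpoints keep the achieved specificity interpretable as k/n. A sample
is score-positive if any defined region exceeds its threshold; samples
undefined in all regions are scored negative and flagged
(negative-by-absence) so users can exclude them instead. Threshold sets
serialize to JSON and transfer between cohorts byte-identically.

**CA125.** Dichotomized at ≥ 35 U/mL. Without an index-date
measurement: abnormal-before ⇒ positive, normal-after ⇒ negative,
anything else excluded (dropped per-analysis, not globally). Combined
marker = OR of the two calls; an excluded CA125 excludes the combined
call.

**Statistics.** Sensitivity/specificity are x/n with exact two-sided
Clopper-Pearson bounds (beta quantiles; lower = 0 at x = 0, upper = 1
at x = n), displayed to one decimal in percent. ROC/AUC uses the
empirical curve with tied scores grouped; AUC is the normalized
Mann-Whitney statistic and is cross-checked in tests against explicit
pair counting and scikit-learn. The paired-difference interval is
Δ ± t_{α/2,N−1}·S_D/√N with S_D the sample standard deviation of the
differences; the published description of S_D as a standard error is
internally inconsistent with the √N division, so the standard paired-t
reading is the default and an `sd_is_se` switch implements the literal
one. Day/night concordance reports Pearson r separately for pairs whose
mean lies above vs at/below 1% fully methylated reads (undefined below
3 pairs or for constant vectors) plus the count of positive/negative
call flips. No multiplicity correction is applied anywhere.

**Contamination stratification.** Ratio = cfDNA window mass / gDNA
window mass; zero gDNA mass is flagged infinite and sorts above every
finite ratio. The cohort median (midpoint convention for even n) splits
samples into higher (ratio ≤ median) and lower (ratio > median)
contamination groups, recomputed within each cohort.

## Cohort designs

Defaults mirror the two study populations. Diagnostic: 41 controls
(4 healthy, 37 benign) and 27 cancers with grades 5/1/19/2
(1/2/3/unknown) so 20 are high risk, stages 3/1/10/7 (+6 unknown),
CA125 log-normal with median 14 (controls) and 152 U/mL (cases) and σ
set from the reported interquartile ratios (the reported case IQR is
not log-symmetric, so the calibration pins the median and the quartile
ratio, not each quartile). Early detection: 29 matched case-control
pairs, 27/29 cases high risk, BRCA1/2 carrier counts as published,
CA125 medians 12 and 34 U/mL, and ten-fold higher gDNA contamination
(log-normal, median ratio 1.0 vs 0.1) reflecting archival storage.
Within-group draws that the study does not constrain are the package's
own choices, made once: case tumor fractions log-normal with median 2%
(diagnostic) and 0.2% (pre-diagnosis), σ = 1; per-subject epimutation
rates log-normal with median 0.2%, σ = 1; days from sampling to
diagnosis log-normal with median 600 d, σ = 1, so a realistic minority
of pre-diagnosis samples fall within a year of diagnosis (the published
"time to event" is follow-up from enrollment and does not pin this).
CA125 availability fractions match the published counts; unavailable
subjects receive one displaced measurement so the temporal-imputation
rules are exercised.

## Problem sizes and numerical choices

Library defaults use 220 bp amplicons with six CpGs and 150–200 read
pairs per region per sample; examples and the acceptance script run the
full cohorts at depth 100–150, and the exhaustive-oracle and
closed-form checks use 1,000 and 20,000 fragments respectively. These
are desk-scale settings chosen so a complete rerun takes minutes on one
CPU; the statistical structure (counts, rates, granularities) does not
depend on depth beyond sampling noise. All randomness flows through
`numpy.random.default_rng` seeds; per-sample seeds are spawned from one
master seed via `SeedSequence`, and every stochastic output is
byte-identical under a repeated seed (gzip members are written with a
fixed mtime for this reason). Percentages are displayed to one decimal.

## What passing tests do and do not show

The simulator reproduces the *statistical structure* the analysis
assumes — fragment origin mixtures, bisulfite chemistry error, uniform
sequencing error, contamination dilution, log-normal marker
distributions — not the messiness of real plasma libraries: no PCR
duplicates or amplification bias, no indels, no per-base quality
variation, no NovaSeq error profile, uniform random off-target sequence
rather than real genomic background, and synthetic amplicon sequences
rather than the true marker loci. Tests passing here certify the
pipeline's contracts (exact truth recovery without chemistry noise,
aligner optimality, calibration granularity, interval exactness,
OR-rule set inclusions), and that the published exact intervals follow
from their counts; they say nothing about clinical performance on real
specimens. The cohort-level sensitivities of the original study cannot
be recomputed without the patient-level data, which are not public.
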