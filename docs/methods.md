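# Methods

This note documents the models, statistics and design choices behind
`estrpipe`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic cohorts do and do not emulate.

## Panel construction

STRs are defined as perfect tandem runs of a primitive 1–6 bp motif.  The
detector performs an exhaustive linear scan per unit size `u`
(`seq[k] == seq[k-u]`), reports maximal runs truncated to whole units, and
requires a minimum allele length of 9, 4, 4, 3, 3 and 3 units for mono- to
hexanucleotide repeats respectively.  Only perfect repeats are annotated;
imperfect-repeat harmonisation (divergence models, profile HMM
re-annotation) is out of scope, and the exhaustive perfect scan already
captures the low-complexity runs that dominate STR mutation in tumours.

Motifs are stored in canonical form — the lexicographically smallest string
among all rotations of the motif and of its reverse complement — so locus
identity is phase- and strand-independent.  Coordinates are 0-based
half-open throughout; GFF3 input is converted from 1-based closed.

Overlap resolution keeps, within any overlapping cluster, the candidate
with the smallest unit size, then the longest span, then the smallest
start.  The proximity filter removes *both* members of any pair of loci
separated by ≤ 50 bp (the gap rule is inclusive; the choice to drop both
neighbours rather than one is ours — it is the conservative reading and
keeps the filter symmetric).  Region labels follow the priority
CDS > UTR > intron > promoter, where the promoter is the 5 kb window
upstream of the gene's strand-aware 5′ end; loci outside every labelled
region are dropped because only gene-associated sequence is genotyped.
Loci on non-autosomes or overlapping a user-supplied mask BED (e.g.
segmental duplications) are removed.

## Genotype I/O and quality filters

Calls are biallelic allele lengths in repeat units.  The allele pair is
unordered and serialized ascending, so genotype identity never depends on
caller allele order.  Filters mirror standard post-genotyping QC: per-call
read depth must lie in [20, 1000] (calls lacking a depth value — synthetic
data — pass), samples with fewer than 10,000 called loci are discarded, and
tumour calls whose locus overlaps (≥ 1 bp, half-open) a somatic CNV segment
of the same sample are removed to avoid dosage confounding.  CNV overlap
uses the locus interval itself, unpadded.

## Somatic mutation calling

A locus is somatically mutated when the tumour allele multiset differs from
the patient-matched healthy multiset; the healthy reference is the healthy
sample with the most calls (ties prefer blood-derived normals).  Tumour
calls homozygous for an allele absent from the healthy pair are excluded as
putative allele dropout and counted separately.  Per-allele step sizes pair
the sorted healthy with the sorted tumour alleles positionally, which
minimises the total absolute step for a diploid pair (a parsimony choice;
no pairing is observable from length data alone).  Mutation detection and
per-patient fractions are locus-level; the step-size histogram is
per-allele.  Whether a published step histogram counts loci or alleles is
generally ambiguous; per-allele resolution is our choice and is stated
wherever the histogram is emitted.

MSS/MSI concordance of the deletion ranking is summarised as the AUC of the
MSI label against the per-patient deletion fraction (Mann–Whitney U scaled
by the product of group sizes).

## Mutability statistics

Comparisons (locus × patient, with a mutated flag) are pooled across
patients and stratified by unit size and by healthy allele length (mean of
the healthy pair, rounded half-up; using the healthy mean rather than the
panel reference length is our choice for the length stratification, since
it reflects the allele actually at risk).  MSS-vs-MSI contrasts use
two-sided Fisher exact tests on the pooled 2×2 table.  Pooling treats
comparisons as independent Bernoulli trials and ignores within-patient
clustering — a deliberate simplification; p-values for strongly clustered
data will be anti-conservative and should be read as descriptive.
Allele-length strata are reported only when at least 50 distinct patients
contribute a comparison.

## eSTR discovery

Expression (TPM) is restricted to genes with nonzero median across the
discovery tumours and rank-inverse-normal transformed per gene:
`Φ⁻¹((rank − 0.5)/n)` with average ranks for ties.  The plain `(i − 0.5)/n`
offset (no Blom constant) is used — simple, symmetric, and exactly
order-preserving.  Genotypes enter as the mean of the two tumour allele
lengths.  Eligible loci are called in ≥ 50 patients with ≥ 3 distinct mean
genotypes; STR–gene pairs are formed for every gene whose body (plus the
5 kb promoter window; inclusion of the window is our choice, exposed as a
flag) contains the locus, so one locus may test against several genes.

Each pair is fit by ordinary least squares of normalized expression on mean
genotype with a two-sided t-test of the slope (n − 2 df); the closed-form
fit is verified against the `statsmodels` OLS implementation in the test
suite.  Benjamini–Hochberg controls the FDR at α = 0.05 across all fitted
pairs.  The negative control permutes each pair's genotype vector across
samples once and refits, yielding one permuted p-value per pair for Q-Q
comparison — a calibration control, not a per-pair permutation p-value.
Covariate adjustment (purity, structure, expression factors) and
fine-mapping of linked variants are out of scope.

## Validation by direction of expression change

Held-out patients with matched tumour and adjacent-normal expression are
mapped onto the discovery scale using stored per-gene reference quantiles
(the sorted raw TPM vector of the discovery samples): the empirical
quantile of a new value uses mid-ranks for exact matches and linear
interpolation between neighbours, clamped to `[0.5/n, 1 − 0.5/n]` before
`Φ⁻¹`.  Re-normalizing a discovery sample through its own reference
reproduces its discovery score exactly in the tie-free case (tested to
1e-9).

For each somatic mutation at a significant eSTR, `sign(β · Δ_l)` predicts
the direction of expression change, where `Δ_l` is the tumour-minus-healthy
difference in mean allele length.  The expected impact is `|β| · |Δ_l|` —
the magnitude is unsigned; direction is carried separately.  Records with
`β · Δ_l = 0` or an exactly zero observed change are excluded from accuracy
and reported as ties.  Overall accuracy is tested against chance with a
one-sided exact binomial test (p = 0.5, alternative "greater"), and
accuracy is additionally reported within quartiles of expected impact
(stable sort; ties keep input order).

## Repeat-type mutability permutation test

Loci entering the eSTR analysis are grouped into repeat types (unit size ×
panel reference allele length — the reference length read literally, not
the patient's healthy length).  Within each type the mutated fraction of
eSTR observations is compared with that of non-eSTR observations; one
observation is one locus × patient comparison.  Types with fewer than 25
observations on either side are discarded, and a difference must strictly
exceed 0.05 to count (0.41 vs 0.38 is "no difference").  The statistic —
the fraction of tested types where eSTRs are more mutable — is compared
with a null built from 10,000 global shuffles of the eSTR labels across the
eligible loci (the shuffle preserves the total eSTR count but not per-type
counts; the full analysis, including the discard rule, is recomputed per
shuffle).  The add-one estimator `p = (1 + #{null ≥ obs})/(1 + n_perm)`
avoids p = 0 and gives a minimum of 1/10001 at 10,000 permutations.  MSS
and MSI cohorts are analysed fully separately; the symmetric
"non-eSTRs more mutable" statistic is computed the same way.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
sequencing itself.  Per patient, healthy biallelic genotypes are the panel
reference length plus small germline offsets (−2…+2 units, mode 0).  Each
tumour allele mutates independently with probability
`base_rate · (1 + slope · (L − L_min))`, non-decreasing in allele length
(`base_rate` 0.005 per allele, slope 0.15 per unit by default — chosen so a
matched MSS cohort shows ~1–2% of loci mutated per patient and an MSI
cohort several-fold more, the regime reported for colorectal tumours).
Step magnitudes follow a geometric-like decay with P(±1) ≈ 0.55, matching
the observation that single-step changes dominate; the empirical step
distribution is not published numerically, so these defaults are
qualitative.  The MSI phenotype multiplies the deletion rate only (default
×10, mirroring the reported >10:1 deletion:insertion excess), leaving
insertion rates at the MSS level; deletions never take an allele below one
unit.  A configurable fraction of heterozygous loci is emitted in the
tumour as homozygous for a novel allele to exercise the dropout filter.
Double-hit mutations that would leave the tumour homozygous for an unseen
allele are nudged one extra step so planted truth and callable events
coincide exactly.

Planted eSTR genes receive latent expression
`intercept + β · mean_allele_length + N(0, noise_sd)` (β magnitudes drawn
from [0.5, 1.5] with random sign; noise SD 1) mapped to a nonnegative
TPM-like scale by a unit-scale softplus — monotone, so planted signs
survive normalization; an identity transform is available for exact-linearity
tests.  All other genes are genotype-independent, and a small fraction is
silent (all-zero) to exercise the expressed-gene filter.  Per-sample CNV
segments cover ~17% of loci in MSS tumours and ~1.3% in MSI tumours, the
reported proportions of CNV-overlapping calls.  Random streams are split
per patient (derived from the seed and the patient index), so enlarging the
cohort never reshuffles earlier patients; draws within a patient are
vectorized over loci.

What the generator does **not** emulate: read-level error, reference bias,
stutter noise in length calls, linkage between loci, covariance structure
in expression, tumour purity, or subclonality.  Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under the
stated generative model, not robustness to those real-data complications.

## Problem sizes used in the checked examples

The acceptance-style checks run at desk scale: discovery cohorts of 300
tumours × 2,000 loci with 150 planted eSTRs; null calibration over 10
seeds at 150 tumours × 1,000 loci; validation on 60 MSI-like held-out
patients (~900 usable eSTR mutations, mirroring the order of the real
validation set); permutation-test calibration over 50 seeds of a 20-patient
MSI cohort with exchangeable labels at 400 permutations, plus one full
10,000-permutation run.  These sizes make every property measurable with
comfortable statistical margins while keeping a full run in minutes on one
CPU.

## Numerical and degenerate-input conventions

Constant expression vectors transform to all-zero scores (average ranks).
Zero genotype variance, cohorts with a single MSI label, fewer than three
distinct tumour stages, empty strata and zero usable validation records are
flagged as errors or NaN rather than silently computed.  BH q-values are
monotone; `q ≥ p` always.  The permutation-test statistic for a shuffle in
which no repeat type passes the observation threshold is counted as 0.
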