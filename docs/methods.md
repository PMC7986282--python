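# Methods

This note documents the models and procedures the toolkit implements, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and gene anchors

All coordinates are 0-based half-open internally; emitted TSVs are 1-based
inclusive. A gene is anchored at its representative TSS when
transcript-isoform data is available, otherwise at the first base of its
CDS in transcription direction. The representative TSS is the isoform
start with the highest read count; ties are broken toward the TSS nearest
the CDS start, then toward the smaller genomic coordinate, so selection is
deterministic under row permutation. Offsets are signed in the gene's
transcription direction with the anchor at 0.

## Guide design

Candidate targets are 23-nt protospacer+PAM sites (NGG on either strand,
read in protospacer orientation). The target center is the 12th base of
the 23-nt span in genomic order — 23 is odd, so a unique central base
exists. Sites are associated with a gene when the center offset falls in
[−220, +20] for TSS-anchored genes or [−350, 0] for CDS-anchored genes.
A site is *unique* when the 20-nt protospacer followed by any NGG occurs
exactly once in the genome counting both strands (N bases never match,
which is the conservative direction for uniqueness), and *specific* when
exactly one gene's association window contains its center; all other
associated genes are recorded as alternative targets — the ambiguity that
arises at divergently transcribed promoters separated by a few hundred
base pairs. Accessibility is the mean ATAC-style signal over the 23
target bases; replicate tracks are combined by averaging the per-replicate
means, and positions without data read as 0.0 (no evidence of openness).

Selection priority is lexicographic: unique first, then specific, then
higher accessibility. Remaining ties are broken by proximity of the
center offset to −50 (the empirically most active position), then smaller
genomic coordinate, then + strand — the position prior gives tie wins to
guides most likely to work, and the rest guarantees byte-identical
libraries on identical inputs. Selection first takes the best candidate
in each promoter zone ([−220, −141], [−140, −61], [−60, +20] for TSS
genes; [−350, −271], [−270, −191], [−190, −111], [−110, −30] for CDS
genes; empty zones are skipped), then fills with the best remaining
candidates until ten guides or exhaustion. Non-unique candidates remain
eligible at the lowest priority tier rather than being excluded outright.
CDS-mode candidates with centers in (−30, 0] belong to the association
window but to no zone; they compete only in the fill phase.

Ambiguous guides at divergent promoters can be re-assigned using a fitted
position-activity curve: predicted activity for each associated gene is
the depletion magnitude max(0, −curve(offset)), offsets outside the
window count as inactive, and the guide is assigned to the most active
gene when it beats the runner-up by a configurable factor (default 2:1
odds; no principled value is established, so it is exposed as a
parameter).

## Barcode processing

The counting workflow trims the 3′ linker adapter, keeps barcodes of at
least 10 nt, collapses single-substitution neighbors, and filters the
collated table: a barcode must appear in at least 2 libraries, carry at
least 33 reads total, and contain no XhoI site (CTCGAG, the enzyme used
to linearize templates before in vitro transcription — a site inside the
barcode breaks the amplification).

Collapsing is greedy and directional: barcodes are processed by
descending count (ties lexicographic); each either founds a record or is
absorbed by an existing founder of the same length at Hamming distance 1
(the highest-count founder when several qualify). Only substitutions are
collapsed — Hamming distance is undefined across lengths. Founders end
pairwise at distance ≥ 2, so collapsing is idempotent, and member counts
are conserved by construction.

The assignment workflow trims R1 barcodes (≥ 12 nt after the longer
assignment adapter) and R2 guide sequences (≥ 20 nt between fixed 5′ and
3′ adapters). Guide reads with any base below Q30 (Phred+33, applied to
the trimmed guide bases) are discarded as low quality. Remaining reads
are globally aligned against the designed guide sequences plus a
scaffold-only "empty" reference entry; distances above 3 edits are
unmatched, and reads tying between two library guides are excluded from
majority computations to avoid manufacturing heterogeneity. Fates per
collapsed barcode: fewer than 3 high-quality reads → *insufficient*;
majority guide below 90% of usable reads → *heterogeneous*; majority
present but its modal alignment carries edits → *defective* (a tie
between edit-free and edited modal outcomes is conservatively called
defective, while a lone sequencing error among edit-free reads is
tolerated); otherwise *assigned*, or *empty* when the majority is the
scaffold-only entry. The 90% majority is computed over high-quality,
alignable reads; the fates partition all barcodes and the emitted tally
sums to the barcode total.

## Fitness inference

Barcodes are kept when they have at least 64 pre-induction reads in at
least one culture. Size factors are median-of-ratios: the reference per
barcode is its geometric mean across samples (rows with any zero are
excluded from the median), each sample's factor is the median ratio to
the reference, and factors are rescaled to geometric mean 1; when no
all-nonzero barcode exists the code falls back to total-count ratios with
a warning.

Each barcode's counts are fit with a negative-binomial GLM, log link:

    log E[count] = log(size_factor) + b0 + b_gens * gens + b_culture

with gens ∈ {0, 3.75, 7.5, 11.25} and culture a 0/1 indicator for the
second culture (dropped for single-culture input; samples of a culture in
which the barcode was never observed are dropped together with the
indicator rather than driving it to −∞). Dispersion is a per-barcode
method-of-moments estimate from a Poisson pre-fit — solve
Σ[(y−μ)² − μ] = α·Σμ², floored at 1e-8 — a stated, testable estimator
whose misspecification barely moves slope estimates at screen depths.
The fitted gens coefficient is divided by ln 2 (and its Wald standard
error likewise) to give the fitness score on the log2-per-doubling scale.
Technical duplicates at a timepoint enter as additional samples with the
same gens value. Zero counts at late timepoints are left as observed —
the NB likelihood treats them as informative — rather than patched with
pseudocounts.

Guide fitness is Σ(slope_i/se_i²)/Σ(1/se_i²) with standard error
√(1/Σ(1/se_i²)) over converged barcode fits; guides with none are
omitted. The active-guide threshold is the 5th percentile (linear
interpolation) of at least 20 scaffold-only negative-control fitness
values.

## Activity model

The position curve is loess: locally weighted linear regression with a
tricube kernel over the nearest ⌈αn⌉ points, α = 0.25, no robustness
iterations, degree 1; predictions outside the data range clamp to the
boundary fit. Each guide's features are the curve prediction at its
offset (OffsetPred), the minimum occupancy in the 33-nt window covering
the target plus 5 nt on each side (ODM; missing data reads as 1.0, fully
occupied — the pessimistic mirror of the accessibility fill), and 20
categorical protospacer bases dummy-coded with A as the reference level
(3 contrasts × 20 positions, 60 coefficients). Occupancy feeds the model
directly with no sign flip; the logistic coefficient absorbs the
direction. The logistic regression is fit by maximum likelihood; if the
fit is unstable (perfect separation is possible on small synthetic sets)
it falls back to a weak L2 penalty (λ = 1e-4) with a warning, and
standard errors are then not reported.

Cross-validation partitions guides (not barcodes) into k = 10 seeded
random folds and refits *both* stages — loess and logistic — on the
training folds before scoring the held-out fold; pooled held-out scores
give the AUC via the rank (Mann–Whitney) formulation with half credit
for ties. Folds whose training complement would be single-class are
merged with a warning. A strand-specific variant (separate loess per
guide strand) and an ATAC-accessibility feature exist behind flags; the
strand-independent, ODM-only model is the default. Calibration bins
pooled held-out logits into unit-width bins centered on 0 and reports per
bin the median fitness and empirical active fraction; a well-calibrated
model shows ≈ 50% active guides in the logit-0 bin. Calibration on
training scores is in-sample and flagged as such by usage (the CLI uses
cross-validated scores).

## Synthetic data

The genome generator places gene units left-to-right with ≈ 700 bp
between units so association windows of unrelated genes never overlap,
and lays a configurable fraction of genes out as divergent pairs whose
TSSs face away from each other 200–600 bp apart — reproducing the
ambiguous-guide geometry of compact genomes. TSS tables contain a modal
isoform plus up to two weaker isoforms; a configurable fraction of genes
has no isoform rows and falls back to CDS mode. Accessibility tracks
carry a nucleosome-free bump (≈ 0.9) over roughly [−150, +10] around each
TSS on a 0.05 background, in two jittered replicates; occupancy is the
mirrored signal. Sequence is i.i.d. with adjustable GC content.

The screen generator gives each guide a Poisson(+1) number of barcodes
(mean 4), log-normal initial abundances shared across the two replicate
cultures (both are inoculated from one transformant pool), and evolves
lineage frequencies as f_i(g) ∝ f_i(0)·2^(fitness_i·g), renormalized each
timepoint and sampled multinomially at the configured depth per sample.
Default true fitness is a bimodal mixture — 60% of guides exactly neutral,
40% active with fitness uniform on [−1, −0.1] — matching the observed
structure of screen fitness distributions in which most guides are
ineffective. This is not merely cosmetic: median-of-ratios normalization
(like every count-based screen analysis) assumes a majority of unchanged
features, and a pool in which every guide is deleterious would shift all
inferred slopes by the pool median. About 1% of barcodes are guide-free
scaffold-only constructs with true fitness 0, serving as negative
controls. Sampling is multinomial; a Dirichlet-multinomial mode is not
currently implemented, so technical overdispersion beyond counting noise
is not emulated.

The read generator plants barcode fates at the characterized rates
(10% synthesis errors, 5% chimeras, 1% guide-free) with the real adapter
structure and Phred+33 qualities: Q38 baseline, Q20 at sequencing-error
positions, plus occasional low-quality error-free bases to exercise the
Q30 filter. Synthesis errors are substitutions or single-base insertions;
a clean single deletion would leave a 19-nt variable region that the
20-nt trim filter discards, surfacing as low coverage rather than a
defective call, so deletions are exercised in the assignment-rule unit
tests instead. Chimeric barcodes split their reads ~50/50 between two
guides; with few reads such a barcode can by chance look homogeneous,
which keeps recovered rates within binomial error of the planted rates
rather than exactly equal.

The efficacy generator draws offsets uniformly over [−220, +20], builds
occupancy as 1 − 0.8·a(offset) plus independent noise where a(·) is a
Gaussian activity bump centered at −50 (width 45 nt), and draws activity
from the logistic law η = −1.5 + 4.5·a − 3.0·odm. Fitness is then drawn
from a strongly negative component for active guides and a near-neutral
component for inactive ones, on either side of the −0.38 activity
threshold, so labels derived from fitness agree with the planted ones.
Protospacer sequences are random and carry no signal, which is used to
check that an uninformative feature does not materially inflate
cross-validated AUC.

### What passing tests do and do not show

The generators emulate the statistical structure the pipeline assumes —
exponential lineage dynamics, counting noise, planted error rates, a
position+occupancy activity law — not real yeast biology: no codon bias
or repeats, no PCR duplicates or fragment-length effects, no biological
overdispersion beyond multinomial sampling, and no real relationship
between sequence features and activity. Tests passing on this data
verify the procedures (filters, estimators, selection logic, model
wiring), not field performance numbers; in particular the published
real-data AUCs and the −0.38 threshold are properties of the real screen
data and are not reproduced here.

## Problem sizes and numerical choices

The test suite and the acceptance script run the design stage on 50-gene
genomes (two 60-kb chromosomes), the fitness stage on 100-guide screens
(≈ 400 barcodes, depths 1e5–1e6), and the efficacy stage on 2000 guides —
sizes at which every check is exact or tightly converged while the whole
suite stays fast. Other numerical choices: loess windows with zero
x-spread fall back to the weighted mean; empty candidate lists yield an
empty (uncovered) selection; windows reaching past chromosome ends are
truncated with a warning; track values are clamped to [0, 1] on load; the
guide aligner is exact edit distance (edlib, global mode), so "perfect"
means edit distance 0.

## Known limitations

* Uniqueness is perfect-match only; no mismatch-tolerant off-target
  scoring.
* The dispersion estimator is deliberately simple; it does not shrink
  across barcodes by default and is not a replacement for tools with
  moderated dispersion when counts are shallow.
* The divergent-promoter resolution margin (2:1 odds) is a pragmatic
  default, not an empirically fitted value.
* Fitness scores are relative to the normalization anchor; if most
  lineages in a pool change abundance, median-of-ratios factors absorb
  part of the signal.
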