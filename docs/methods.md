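# Methods

## Scope and model

`ampliqc` implements the evaluation machinery for variant calls from
amplicon-based exome sequencing on flow-space (semiconductor) platforms:
truth-set benchmarking after normalization, error characterization,
coverage/downsampling analysis, and data-driven hard-filter tuning. The
package contains no caller; calls and truth sets are inputs, and a
synthetic-data module generates complete cohorts with the platform's known
error structure so that every stage can be validated without external data.

## Normalization

Multiallelic records are split into one record per alternate allele;
per-allele annotations (AO, FAO) are routed to the matching record,
site-level annotations copied, and every product carries
`n_original_alts`, the allele count of the originating line. Each
single-alt record is then reduced to its left-most minimal representation
against the reference: shared trailing bases are trimmed (extending both
alleles to the left with the reference base when one would empty — this
walks indels leftward through repeat context), then shared leading bases
beyond the single VCF anchor are trimmed. The result is
haplotype-equivalent to the input and idempotent; both properties are
asserted against brute-force oracles and against `bcftools norm` in the
test suite. Normalized variants keep `source_pos`, the POS of the
originating line, so split siblings of one multiallelic record can be
grouped back together after left-alignment moves them to different
positions (multiallelic-origin fractions are counted per original record,
not per normalized row).

Region restriction keeps a variant iff its normalized POS (0-based) lies in
the region set; the full REF span is deliberately ignored so boundary
indels behave deterministically. All interval arithmetic is strand-free,
0-based half-open, canonical (sorted, merged); book-ended intervals merge.

## Benchmarking

Matching is exact on `(chrom, pos, ref, alt)` after normalization,
separately for SNPs (both alleles length 1) and indels (allele lengths
differ); equal-length multi-base substitutions are reported as `complex`
and excluded from both classes. Genotype/zygosity is ignored — concordance
is allele-level. Conventions for degenerate denominators: an empty
evaluated truth set is an error (it cannot arise from the generator); with
zero calls, precision is reported as 1 with a warning and F1 as 0.
The low-depth threshold for FN accounting is 10 reads at the variant
position (depth taken from the bedGraph value at POS); FN sites without
depth data are counted separately as `unknown`, never folded into the
low-depth fraction.

## Coverage statistics

`breadth_k` is the fraction of target bases with depth ≥ k (default 20);
uniformity the fraction with depth ≥ 20 % of the sample mean; the IQR of
base depth uses the median-unbiased quantile convention (recorded in the
output). Bases absent from a track count as depth 0 in summaries but are
distinguishable (`value_at` returns `None`). Reads are assigned to
amplicons by maximal overlap, ties to the left-most amplicon; per-amplicon
mean depth is the per-base mean within the amplicon. GC classes: high
> 0.75, low < 0.25. An exon is `always_low` when its mean depth is < 10 in
every sample of a cohort, and `partial_f` (f ∈ {0.5, 0.25, 0.1}) when its
covered fraction (bases with depth ≥ 1) is below f in every sample; the
partial classes are nested by construction.

Downsampling keeps each read independently with probability
`target_mean / current_mean` and recomputes depth from the retained reads.
A variant is counted lost when its post-thinning site depth falls below 20
— an emulation anchored to the breadth_20 statistic, not a caller
re-implementation. The two downsampling relationships are fitted by least
squares: `breadth_20(mean) = 1 − exp(−(mean − m₀)/τ)` (predictions clipped
to [0, 1]; fitted on the observed levels only, no extrapolation claims) and
`variant_loss = a + b · breadth_20`; a constant series yields undefined
(NaN) r². Parameter recovery (m₀, τ within 15 % on noisy synthetic series)
is part of the test suite.

## Filter tuning

A filter is a five-threshold vector per class (SNP: GQ, FDP, QUAL, STB,
FAO; indel: GQ, FDP, QUAL, HRUN, FAO). Removal is the OR of failing
conditions — `GQ < GQ_min`, `FDP < FDP_min`, `QUAL < QUAL_min`,
`FAO < FAO_min`, and `STB > STB_max` (SNP) or `HRUN > HRUN_max` (indel); a
call is retained only when it passes every threshold. Calls missing a
required parameter are removed with the distinct label `ts_missing` and
counted separately. Raising any `_min` (or lowering any `_max`) can only
shrink the retained set, and filtering is idempotent; both invariants are
exercised over hundreds of random specs.

`FilterTuner` searches the grid exhaustively. Candidate thresholds per
parameter are the 11 deciles (0, 10, …, 100 %) of the training TP
distribution plus the shipped preset threshold for the targeted stringency
(≤ 12⁵ ≈ 249k combinations; prefix-AND masks keep a full search under a
second at 12k calls). Feasible combinations retain at least the target TP
fraction — the all-permissive grid point (TP minima / maxima) always
qualifies, so feasibility is guaranteed. Among feasible combinations the
tuner maximizes FP removal; ties break toward higher TP retention, then
toward more permissive thresholds in the fixed order GQ, FDP, QUAL,
HRUN/STB, FAO, making the selection deterministic. Retention is enforced
pooled over the training calls by default; `per_sample=True` enforces it
within each sample. The published preset thresholds for the three
stringency levels are shipped as provisional configuration defaults
(grid anchors and starting points), not constants the tuner depends on.

Advisory indel flags (never removals): `multiallelic_suspect`
(`n_original_alts ≥ 3`), `long_indel_suspect` (length > 100 bp),
`homopolymer_context` (caller HRUN ≥ 5).

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is validated under.

**Reference and regions.** One chromosome; exon lengths log-normal
(μ = ln 190, σ = 0.55, bounded [60, 440] bp) so roughly 60 % of exons fit a
single amplicon; each exon is tiled by 1–2 amplicons of 156–240 bp;
intergenic gaps uniform 100–400 bp. A configured fraction of amplicons is
designated high-GC (> 0.75; default 1.9 %) or low-GC (< 0.25; default
0.7 %), matching the shares observed on a ~294k-amplicon design, and their
sequence is drawn at the corresponding base composition; homopolymer runs
(6–12 bp) and triplet repeats are planted inside mid-GC exons. `targets`
is the merged amplicon footprint, `high_confidence` the footprint trimmed
by 2 bp per interval end, and the evaluation region their intersection.

**Truth set.** SNP:indel composition defaults to the 15,811 : 325 ratio
scaled by proportional rounding (1000 → 980/20). Positions are drawn
without replacement with ≥ 15 bp spacing inside the evaluation region;
indels (80 % of them 1–2 bp) are left-aligned at generation so the truth is
already canonical.

**Depth.** Each amplicon gets a cohort-level efficiency, log-normal with
σ = 1.2 — wide enough that a realistic share (~5–8 %) of target bases sits
below 10 reads while breadth_20 at the default 120× mean stays in the
observed range — times a high-GC dropout factor
`exp(−gc_dropout_strength · penalty)` (penalty 0.7 for high-GC amplicons, 0
otherwise; strength default 3, giving high-GC median depth roughly one
order below mid-GC, and no low-GC penalty). Read counts per amplicon are
Poisson with the scale normalized to the drawn efficiencies so the
expected genome-wide mean equals the configured coverage; reads span their
amplicon exactly (read-level realism — sequences, qualities, flow signals,
BAMs — is out of scope).

**Call sets.** Per sample (independent stream from (seed, sample index)):
false negatives are Bernoulli per truth site with stratified probabilities
p_low (sites with depth < 10) and p_high solved so the overall rate equals
`fn_rate` and the expected share of FN at low-depth sites equals the
configured fraction (SNPs default 0.33, indels 0.165 — the two classes
differ in the observed data, so the generator keeps separate knobs; p_low
is clamped at 1 with a warning when too few low-depth sites exist).
False positives are planned cohort-wide: each distinct FP is private to one
sample with probability `fp_unique_fraction` (default 0.71) or shared by
k ~ Uniform{2..n_samples} samples, with the planned count chosen so the
expected per-sample FP load matches `fp_per_sample_*`; a configured
fraction of FP indels (default 0.10) is emitted as one multiallelic record
with three alternate alleles of different lengths. Default per-sample
error rates (fn 0.05 SNP / 0.35 indel; 60 FP SNPs and 12 FP indels against
980/20 truth) reproduce the platform's reported regime of accurate SNPs
and indel FDR approaching one half.

**Annotations.** The 11 caller parameters are drawn from class-conditional
families (truncated log-normal for GQ/QUAL, beta for FXX/STBP, a balanced
half-normal vs one-sided beta for STB, shifted Poisson for HRUN; DP is the
site depth, FDP ≈ 0.85–0.98 × DP, TP FAO ≈ Beta(12,14) × FDP vs FP FAO of
1–3 reads, QD = QUAL/DP). The parameters live in
`SimConfig.annotation_model`, not in code; the defaults are modelling
choices that reproduce the qualitative TP/FP separations, since no
parametric forms are published for these distributions.

**Bookkeeping.** A sidecar label table records every emitted call's
normalized key, label, originating record position and annotation block;
benchmarking a synthetic cohort must (and in tests does) recover these
labels exactly, and |TP| + |FN| equals the truth count for every sample.
Identical config + seed reproduces every artifact byte-for-byte.

## What the generator does and does not show

Passing tests demonstrate that the pipeline's bookkeeping, statistics and
optimization are correct under a cohort whose *structure* matches the
platform's error profile. They do not demonstrate calling accuracy on real
data: reads carry no sequence or quality information, annotation
distributions are parametric stand-ins, truth/call representation
differences beyond left-alignment (haplotype-equivalent complex
representations) do not occur, and contig structure is a single synthetic
chromosome. Tuned thresholds transfer to real data only insofar as the
real annotation distributions resemble the configured families.

## Problem sizes

The shipped test suite and the reproduction script use: a ~3.2 Mb design
(3,600 exons) with ~10,500 truth variants per class and 2,000 FP per class
for tuning (one training sample, pooled retention); a 9-sample cohort at
default rates (3,000 SNPs / 600 indels, 150 FP each per sample) for the
error-structure fidelity checks; 100-replicate thinning experiments at
10,000 reads for the downsampling bands; and 1,000 randomized indel
representations for normalization. These sizes make every stochastic check
a comfortable binomial/CLT 99 % band while keeping a full run inside a few
minutes on one CPU.

## Known limitations

- Exact-key matching after left-alignment does not credit
  haplotype-equivalent complex representations (no vcfeval-style local
  realignment).
- The callability rule for downsampling (site depth ≥ 20) is a proxy for a
  caller re-run.
- The exponential breadth fit is an empirical summary; m₀ can be negative
  on series whose breadth is already high at the lowest level.
- With very few low-depth truth sites the FN depth structure clamps
  (warned) and the realized low-depth FN share falls below the configured
  value.
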