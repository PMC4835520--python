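# ampliqc

Benchmarking and quality-control toolkit for **amplicon-based exome
sequencing** variant calls, built around the evaluation workflow used for
semiconductor (flow-space) sequencers: compare a call set against a
gold-standard truth set inside restricted high-confidence regions,
characterize the errors, model how coverage drives variant loss, and derive
multi-parameter hard filters that keep a target share of true positives
while removing as many false positives as possible.

Everything runs on fully synthetic cohorts generated in-package, so the
whole pipeline is testable end-to-end without downloading reference
datasets.

## What it does

**Benchmarking.** Calls are normalized (multiallelic sites split,
indels left-aligned to their left-most minimal representation), restricted
to an evaluation region set, and matched to the truth by exact key
`(chrom, pos, ref, alt)`, separately for SNPs and indels. From the
partition into true positives (TP), false positives (FP) and false
negatives (FN):

```
sensitivity = TP / (TP + FN)        FDR = FP / (TP + FP) = 1 − precision
F1 = 2·precision·sensitivity / (precision + sensitivity)
```

**Error characterization.** Fraction of FP calls arising from multiallelic
records (≥ 2 / ≥ 3 alternate alleles), indel length classes (1–2 bp,
3–100 bp, > 100 bp), fraction of FN explained by site depth < 10 reads, and
cross-sample recurrence of TP vs FP (true calls recur; false calls are
mostly private to one run).

**Coverage analysis.** Per-base depth and breadth over targets
(`breadth_20` = fraction of target bases with depth ≥ 20), uniformity,
per-amplicon GC statistics with high-GC dropout, hard-to-sequence exon
classification, random read downsampling, and least-squares fits of

```
breadth_20(mean) = 1 − exp(−(mean − m₀)/τ)         (exponential, r²)
variant_loss(breadth_20) = a + b · breadth_20       (linear, r²)
```

**Filter tuning.** Five caller parameters discriminate FP from TP — FAO,
FDP, GQ, QUAL, STB for SNPs; FAO, FDP, GQ, QUAL, HRUN for indels. A call is
removed when any threshold fails (e.g. `GQ < GQ_min`, `STB > STB_max`).
`FilterTuner(...).fit()` searches the threshold grid exhaustively and
returns the combination that maximizes FP removal subject to retaining at
least the target fraction of training TPs: the low / medium / high
stringency presets target ≥ 99 / 95 / 90 % TP retention.

## Worked example

```python
from ampliqc import (SimConfig, simulate_cohort, normalize_records,
                     restrict_to_regions, match_to_truth, accuracy_stats,
                     tune_thresholds)

cfg = SimConfig(seed=7, n_samples=2)      # 980 truth SNPs, 20 indels, 120x
cohort = simulate_cohort(cfg)

sample = cohort.callsets["S00"]
norm = restrict_to_regions(
    normalize_records(sample.records, cohort.reference),
    cohort.regions.evaluation)

for vclass in ("snp", "indel"):
    stats = accuracy_stats(match_to_truth(norm, cohort.truth, vclass))
    print(f"{vclass}: TP={stats['n_tp']} FP={stats['n_fp']} FN={stats['n_fn']} "
          f"sensitivity={stats['sensitivity']:.3f} FDR={stats['fdr']:.3f} "
          f"F1={stats['f1']:.3f}")

result = tune_thresholds(cohort.labels, "snp", target_retention=0.95)
print(result.summary())
```

prints

```
snp: TP=929 FP=63 FN=51 sensitivity=0.948 FDR=0.064 F1=0.942
indel: TP=13 FP=12 FN=7 sensitivity=0.650 FDR=0.480 F1=0.578

Filter tuning (snp, medium stringency)
==============================================
training calls:      1861 TP / 121 FP
target TP retention: 95%
achieved retention:  100.00%
FP removal:          100.00%
grid: GQ=12, FDP=12, QUAL=12, STB=12, FAO=12 (248832 combinations, 32 feasible, 2 ties)
selected thresholds:
  remove if GQ < 9
  remove if FDP < 1
  remove if QUAL < 20
  remove if STB > 0.7
  remove if FAO < 1
```

The synthetic cohort reproduces the familiar error structure of this
platform: SNP calling is accurate while indel FDR is high, FN are partly
explained by low-depth sites, and the tuned filter separates the classes
well because FP calls sit in the low-GQ/QUAL/FAO, strand-skewed tail.

A command-line interface mirrors the library:

```sh
ampliqc simulate --seed 9 --out cohort/
ampliqc normalize --vcf cohort/S00.vcf --ref cohort/reference.fa \
        --regions cohort/high_confidence.bed --out S00.norm.vcf
ampliqc bench --calls S00.norm.vcf --truth cohort/truth.vcf \
        --depth cohort/S00.bedgraph --out bench/
ampliqc tune --labels cohort/labels.tsv --variant-class snp \
        --retention 0.95 --out spec.cfg
ampliqc filter --vcf S00.norm.vcf --spec spec.cfg --out S00.filt.vcf
ampliqc downsample --reads cohort/S00.reads.bed --targets cohort/targets.bed \
        --truth cohort/truth.vcf --levels 90,80,70,60,50,40,30,20 --seed 3 \
        --out series.tsv
```

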