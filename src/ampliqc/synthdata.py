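"""Fully synthetic amplicon-exome cohorts for end-to-end testing.

The generator emulates the statistical structure of variant calling on a
semiconductor amplicon-exome run without any external data: a reference with
planted homopolymer runs, triplet repeats and GC-extreme amplicon blocks;
region sets (CDS exons tiled by 1-2 amplicons of 156-240 bp, a merged target
footprint and a high-confidence subset); a truth set dominated by SNPs
(15,811 : 325 SNP:indel composition, scaled); per-sample read placements and
depth with strong per-amplicon dispersion and high-GC dropout; and annotated
call sets in which false positives are mostly run-specific (71 % private to
one sample by default), enriched for low GQ/QUAL/FAO, strand-skewed STB and
long homopolymer context, with a configurable share of FP indels emitted as
multiallelic (>= 3 alt) records, and false negatives partly explained by
site depth below 10 reads.

Every output is reproducible byte-for-byte from the master seed; each sample
draws from its own stream derived from (seed, sample index) so samples are
independent and recurrence analysis is meaningful.  A sidecar label table
records the exact TP/FP/FN partition the benchmarking stage must recover.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .covstats import DepthTrack
from .regions import GenomicInterval, IntervalSet, write_bed, write_bed_records
from .vcfnorm import NormalizedVariant, VariantRecord, left_align, split_multiallelic, write_vcf

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "SyntheticCallset",
    "default_annotation_model",
    "truth_composition",
    "make_reference",
    "make_region_sets",
    "make_truth_variants",
    "make_depth_and_reads",
    "make_callset",
    "simulate_cohort",
    "write_fasta",
    "RegionBundle",
]

CHROM = "chr1"

#: SNP:indel composition of the reference truth set the generator scales.
TRUTH_SNP_COUNT = 15811
TRUTH_INDEL_COUNT = 325


def truth_composition(n: int) -> Tuple[int, int]:
    """Scale the default truth composition to ``n`` variants by proportional
    rounding: (n_snps, n_indels)."""
    total = TRUTH_SNP_COUNT + TRUTH_INDEL_COUNT
    snps = round(n * TRUTH_SNP_COUNT / total)
    return snps, n - snps


def default_annotation_model() -> Dict[str, Dict[str, tuple]]:
    """Class-conditional distribution parameters for the caller annotations.

    Families are truncated log-normal / beta / Poisson; the numbers here are
    modelling choices that reproduce the qualitative separations between
    true- and false-positive calls (TP: high GQ/QUAL/FAO, balanced strands;
    FP: low GQ/QUAL/FAO, strand-skewed STB, long homopolymer context for
    indels).  They live in configuration so studies can reshape them without
    touching code.
    """
    return {
        "GQ": {"tp": ("lognormal", 4.0, 0.5), "fp": ("lognormal", 1.6, 0.8)},
        "QUAL": {"tp": ("lognormal", 5.5, 0.7), "fp": ("lognormal", 3.0, 0.8)},
        "FXX": {"tp": ("beta", 1.0, 40.0), "fp": ("beta", 2.0, 20.0)},
        "STB": {"tp": ("stb_balanced", 0.06), "fp": ("stb_skewed", 4.0, 1.5)},
        "STBP": {"tp": ("uniform", 0.05, 1.0), "fp": ("beta", 1.0, 15.0)},
        "HRUN_snp": {"tp": ("poisson", 0.8, 0), "fp": ("poisson", 1.2, 0)},
        "HRUN_indel": {"tp": ("poisson", 1.0, 0), "fp": ("poisson", 2.0, 4)},
        "FAO_fraction_tp": ("beta", 12.0, 14.0),   # FAO = fraction * FDP
        "FAO_fp": ("poisson", 1.5, 1),
        "FDP_fraction": ("uniform", 0.85, 0.98),   # FDP = fraction * DP
        "AO_jitter": ("uniform", 0.9, 1.05),       # AO = jitter * FAO
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 1
    genome_length: int = 800_000
    n_exons: int = 900
    amplicon_length_range: Tuple[int, int] = (156, 240)
    # fractions of amplicons designated high-GC (>0.75) / low-GC (<0.25);
    # defaults follow the observed shares (5458 and 2156 of ~294k amplicons)
    gc_block_spec: Dict[str, float] = field(
        default_factory=lambda: {"high": 0.019, "low": 0.007})
    n_truth_snps: int = 980
    n_truth_indels: int = 20
    n_samples: int = 9
    fn_rate_snp: float = 0.05
    fn_rate_indel: float = 0.35
    fp_per_sample_snp: int = 60
    fp_per_sample_indel: int = 12
    fp_unique_fraction: float = 0.71
    multiallelic_fp_indel_fraction: float = 0.10
    low_depth_fn_fraction: float = 0.33          # SNPs (reported 26-41 %)
    low_depth_fn_fraction_indel: float = 0.165   # indels (reported 10-23 %)
    mean_coverage: float = 120.0
    gc_dropout_strength: float = 3.0
    # per-amplicon efficiency dispersion (log-normal sigma); wide enough that
    # a realistic share of sites sits below 10 reads while breadth_20 at the
    # default mean stays in the observed range
    amplicon_dispersion_sigma: float = 1.2
    # reference texture
    n_homopolymers: int = 30
    homopolymer_length_range: Tuple[int, int] = (6, 12)
    n_triplet_repeats: int = 30
    # exon length model (log-normal, bounded); ~60 % of exons fit one amplicon
    exon_length_log_mu: float = math.log(190.0)
    exon_length_log_sigma: float = 0.55
    exon_length_bounds: Tuple[int, int] = (60, 440)
    intergenic_gap_range: Tuple[int, int] = (100, 400)
    min_variant_spacing: int = 15
    annotation_model: Dict[str, object] = field(
        default_factory=default_annotation_model)

    def __post_init__(self) -> None:
        probs = {
            "fn_rate_snp": self.fn_rate_snp,
            "fn_rate_indel": self.fn_rate_indel,
            "fp_unique_fraction": self.fp_unique_fraction,
            "multiallelic_fp_indel_fraction": self.multiallelic_fp_indel_fraction,
            "low_depth_fn_fraction": self.low_depth_fn_fraction,
            "low_depth_fn_fraction_indel": self.low_depth_fn_fraction_indel,
            **{f"gc_block_spec[{k}]": v for k, v in self.gc_block_spec.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if sum(self.gc_block_spec.values()) > 1.0:
            raise ValueError("gc_block_spec fractions sum to more than 1")
        counts = {
            "n_exons": self.n_exons, "n_truth_snps": self.n_truth_snps,
            "n_truth_indels": self.n_truth_indels, "n_samples": self.n_samples,
            "fp_per_sample_snp": self.fp_per_sample_snp,
            "fp_per_sample_indel": self.fp_per_sample_indel,
            "n_homopolymers": self.n_homopolymers,
            "n_triplet_repeats": self.n_triplet_repeats,
        }
        for name, c in counts.items():
            if c < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.amplicon_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid amplicon_length_range")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.gc_dropout_strength < 0:
            raise ValueError("gc_dropout_strength must be >= 0")
        if self.exon_length_bounds[1] > 2 * hi - 8:
            raise ValueError(
                "exon_length_bounds allow exons longer than two amplicons")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), *map(int, stream)])


# RNG stream ids (second word of the seed sequence)
_STREAM_LAYOUT = 0
_STREAM_TRUTH = 1
_STREAM_EFFICIENCY = 2
_STREAM_FP_PLAN = 3
_STREAM_SAMPLE_BASE = 1000


# -- layout and reference -----------------------------------------------------

@dataclass
class _Layout:
    exons: List[Tuple[int, int]]
    amplicons: List[Tuple[int, int, str, int]]   # start, end, name, exon idx
    amplicon_class: List[str]                    # gc class per amplicon
    homopolymers: List[Tuple[int, int, str]]     # start, length, base
    triplets: List[Tuple[int, int, str]]         # start, n units, unit


def _layout(cfg: SimConfig) -> _Layout:
    rng = cfg.rng(_STREAM_LAYOUT)
    min_amp, max_amp = cfg.amplicon_length_range
    exons: List[Tuple[int, int]] = []
    amplicons: List[Tuple[int, int, str, int]] = []
    amp_class: List[str] = []
    cursor = 20
    p_high = cfg.gc_block_spec.get("high", 0.0)
    p_low = cfg.gc_block_spec.get("low", 0.0)
    for i in range(cfg.n_exons):
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        exon_len = int(np.clip(
            round(rng.lognormal(cfg.exon_length_log_mu, cfg.exon_length_log_sigma)),
            *cfg.exon_length_bounds))
        exon_start = cursor + gap + max_amp   # room for left amplicon flank
        exon_end = exon_start + exon_len
        u = rng.random()
        gc_class = "high" if u < p_high else ("low" if u < p_high + p_low else "mid")
        if exon_len <= max_amp - 8:
            amp_len = int(rng.integers(max(min_amp, exon_len + 6), max_amp + 1))
            offset = int(rng.integers(0, amp_len - exon_len + 1))
            spans = [(exon_start - offset, exon_start - offset + amp_len)]
        else:
            f1 = int(rng.integers(0, 5))
            f2 = int(rng.integers(0, 5))
            l1 = int(rng.integers(min_amp, max_amp + 1))
            l2 = int(rng.integers(min_amp, max_amp + 1))
            if l1 + l2 < exon_len + f1 + f2:
                l1 = l2 = max_amp
            if l1 + l2 < exon_len + f1 + f2:
                raise ValueError(
                    f"exon of {exon_len} bp cannot be tiled by two amplicons "
                    f"of at most {max_amp} bp")
            left = (exon_start - f1, exon_start - f1 + l1)
            right = (exon_end + f2 - l2, exon_end + f2)
            spans = [left, right]
        for span in spans:
            amplicons.append((span[0], span[1], f"amp{len(amplicons):05d}", i))
            amp_class.append(gc_class)
        exons.append((exon_start, exon_end))
        cursor = max(s[1] for s in spans)
        if cursor + max_amp + 20 > cfg.genome_length:
            raise ValueError(
                f"genome_length {cfg.genome_length} too small for "
                f"{cfg.n_exons} exons (ran out after {i + 1})")

    # plant homopolymers and triplet repeats inside mid-GC exons
    mid_exons = [exons[i] for i in range(len(exons))
                 if all(c == "mid" for a, c in zip(amplicons, amp_class)
                        if a[3] == i)]
    homopolymers = []
    hp_lo, hp_hi = cfg.homopolymer_length_range
    for _ in range(cfg.n_homopolymers):
        s, e = mid_exons[int(rng.integers(len(mid_exons)))]
        length = int(rng.integers(hp_lo, hp_hi + 1))
        if e - s <= length + 2:
            continue
        start = int(rng.integers(s, e - length))
        base = str(rng.choice(["A", "C", "G", "T"]))
        homopolymers.append((start, length, base))
    triplets = []
    for _ in range(cfg.n_triplet_repeats):
        s, e = mid_exons[int(rng.integers(len(mid_exons)))]
        units = int(rng.integers(3, 7))
        if e - s <= 3 * units + 2:
            continue
        start = int(rng.integers(s, e - 3 * units))
        unit = "".join(rng.choice(["A", "C", "G", "T"], size=3))
        triplets.append((start, units, unit))
    return _Layout(exons, amplicons, amp_class, homopolymers, triplets)


_GC_PROB = {"high": 0.88, "low": 0.12, "mid": 0.47}


def make_reference(cfg: SimConfig) -> Tuple[Dict[str, str], _Layout]:
    """Synthesize the reference sequence with the configured texture.

    Amplicon blocks designated high/low GC are drawn with base composition
    matching their class; homopolymer runs (>= 6 bp) and triplet repeats are
    planted inside mid-GC exons.  Deterministic in the config seed.
    """
    if cfg.genome_length < 10_000:
        raise ValueError("genome_length must be at least 10 kb")
    layout = _layout(cfg)
    rng = cfg.rng(_STREAM_LAYOUT, 1)
    n = cfg.genome_length
    p_gc = np.full(n, _GC_PROB["mid"])
    for (s, e, _name, _ei), cls in zip(layout.amplicons, layout.amplicon_class):
        p_gc[s:e] = _GC_PROB[cls]
    is_gc = rng.random(n) < p_gc
    strand_pick = rng.random(n) < 0.5
    seq = np.where(is_gc, np.where(strand_pick, "G", "C"),
                   np.where(strand_pick, "A", "T"))
    for start, length, base in layout.homopolymers:
        seq[start:start + length] = base
    for start, units, unit in layout.triplets:
        seq[start:start + 3 * units] = list(unit * units)
    return {CHROM: "".join(seq)}, layout


def write_fasta(reference: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass
class RegionBundle:
    """Named region sets of one synthetic design."""

    cds: IntervalSet
    targets: IntervalSet
    high_confidence: IntervalSet
    amplicons: List[Tuple[str, int, int, str]]     # chrom, start, end, name
    amplicon_class: Dict[str, str]                  # name -> gc class
    exons: List[Tuple[str, int, int, str]]          # chrom, start, end, name

    @property
    def evaluation(self) -> IntervalSet:
        """high_confidence ∩ targets — where truth comparisons are valid."""
        return self.high_confidence.intersect(self.targets)


def make_region_sets(cfg: SimConfig, reference=None) -> RegionBundle:
    """Region sets of the design (recomputed deterministically from cfg)."""
    layout = _layout(cfg)
    cds = IntervalSet(GenomicInterval(CHROM, s, e) for s, e in layout.exons)
    amp_records = [(CHROM, s, e, name) for s, e, name, _ in layout.amplicons]
    targets = IntervalSet(GenomicInterval(CHROM, s, e)
                          for s, e, _, _ in layout.amplicons)
    high_conf = targets.shrink(2)
    return RegionBundle(
        cds=cds, targets=targets, high_confidence=high_conf,
        amplicons=amp_records,
        amplicon_class={name: cls for (_, _, name, _), cls
                        in zip(layout.amplicons, layout.amplicon_class)},
        exons=[(CHROM, s, e, f"exon{i:05d}")
               for i, (s, e) in enumerate(layout.exons)],
    )


# -- truth set ----------------------------------------------------------------

def _eval_positions(regions: RegionBundle) -> np.ndarray:
    """All 0-based positions of the evaluation region."""
    ev = regions.evaluation
    starts, ends = ev.spans(CHROM)
    return np.concatenate([np.arange(s, e) for s, e in zip(starts, ends)])


def _spaced_subset(positions: np.ndarray, spacing: int) -> np.ndarray:
    """Greedy left-to-right thinning so consecutive kept positions differ by
    at least ``spacing``."""
    keep = []
    last = -10**12
    for p in positions:
        if p - last >= spacing:
            keep.append(p)
            last = p
    return np.array(keep, dtype=np.int64)


def _draw_positions(cfg: SimConfig, regions: RegionBundle,
                    rng: np.random.Generator, n_needed: int) -> np.ndarray:
    pool = _eval_positions(regions)
    # keep indels away from the outermost bases of the evaluation region
    take = min(len(pool), max(4 * n_needed, n_needed + 64))
    cand = np.sort(rng.choice(pool, size=take, replace=False))
    spaced = _spaced_subset(cand, cfg.min_variant_spacing)
    if len(spaced) < n_needed:
        raise ValueError(
            f"cannot place {n_needed} variants with spacing "
            f"{cfg.min_variant_spacing} in {len(pool)} evaluation bases")
    picked = rng.permutation(spaced)[:n_needed]
    return picked


def _make_snp(seq: str, pos0: int, rng: np.random.Generator
              ) -> Tuple[int, str, str]:
    ref = seq[pos0]
    if ref not in "ACGT":
        ref = "A"
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return pos0 + 1, ref, alt


def _make_indel(seq: str, pos0: int, rng: np.random.Generator
                ) -> Tuple[int, str, str]:
    length = int(rng.integers(1, 3)) if rng.random() < 0.8 else int(rng.integers(3, 9))
    pos = pos0 + 1          # 1-based anchor
    if rng.random() < 0.5:  # deletion
        ref = seq[pos0:pos0 + length + 1]
        alt = seq[pos0]
    else:                   # insertion
        ref = seq[pos0]
        alt = ref + "".join(rng.choice(list("ACGT"), size=length))
    return pos, ref, alt


def make_truth_variants(cfg: SimConfig, reference: Mapping[str, str],
                        regions: RegionBundle) -> List[NormalizedVariant]:
    """Draw the truth set: left-aligned single-alt SNPs and indels, all
    inside high_confidence ∩ targets, at the configured counts."""
    rng = cfg.rng(_STREAM_TRUTH)
    seq = reference[CHROM]
    n = cfg.n_truth_snps + cfg.n_truth_indels
    positions = _draw_positions(cfg, regions, rng, n)
    ev = regions.evaluation
    out: List[NormalizedVariant] = []
    used_keys = set()
    spare = iter(np.setdiff1d(_eval_positions(regions), positions))
    for i, pos0 in enumerate(positions):
        want_snp = i < cfg.n_truth_snps
        pos0 = int(pos0)
        for _attempt in range(200):
            if want_snp:
                pos, ref, alt = _make_snp(seq, pos0, rng)
            else:
                pos, ref, alt = _make_indel(seq, pos0, rng)
            rec = VariantRecord(CHROM, pos, ref, [alt], qual=50.0)
            norm = left_align(rec, reference)
            if (norm.key not in used_keys
                    and ev.contains(CHROM, norm.pos - 1)
                    and set(norm.ref) <= set("ACGT")
                    and set(norm.alt) <= set("ACGT")):
                used_keys.add(norm.key)
                out.append(norm)
                break
            try:
                pos0 = int(next(spare))
            except StopIteration:
                raise ValueError("exhausted candidate positions for truth set")
        else:
            raise ValueError("could not place a truth variant")
    out.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return out


# -- depth and reads ----------------------------------------------------------

_GC_PENALTY = {"high": 0.7, "mid": 0.0, "low": 0.0}


def amplicon_weights(cfg: SimConfig, regions: RegionBundle) -> np.ndarray:
    """Cohort-level relative efficiency of each amplicon: a wide log-normal
    amplicon effect shared by all samples, times the high-GC dropout factor
    exp(-gc_dropout_strength * penalty(GC))."""
    rng = cfg.rng(_STREAM_EFFICIENCY)
    eff = rng.lognormal(0.0, cfg.amplicon_dispersion_sigma,
                        size=len(regions.amplicons))
    penalty = np.array([_GC_PENALTY[regions.amplicon_class[name]]
                        for _, _, _, name in regions.amplicons])
    return eff * np.exp(-cfg.gc_dropout_strength * penalty)


def make_depth_and_reads(cfg: SimConfig, regions: RegionBundle,
                         sample_index: int,
                         weights: Optional[np.ndarray] = None,
                         emit_reads: bool = True
                         ) -> Tuple[Optional[pd.DataFrame], DepthTrack]:
    """Place reads per amplicon and pile them into a depth track.

    Expected read count per amplicon is proportional to its cohort-level
    weight, scaled so the expected genome-wide mean coverage over target
    bases equals ``cfg.mean_coverage``; realized counts are Poisson.  Each
    read spans its amplicon exactly (read-level realism is out of scope).
    """
    if cfg.mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if weights is None:
        weights = amplicon_weights(cfg, regions)
    rng = cfg.rng(_STREAM_SAMPLE_BASE + sample_index, 0)
    lengths = np.array([e - s for _, s, e, _ in regions.amplicons], dtype=float)
    target_bases = regions.targets.total_bases()
    scale = cfg.mean_coverage * target_bases / float((weights * lengths).sum())
    counts = rng.poisson(weights * scale)

    starts = np.repeat([s for _, s, e, _ in regions.amplicons], counts)
    ends = np.repeat([e for _, s, e, _ in regions.amplicons], counts)
    reads = pd.DataFrame({
        "chrom": CHROM, "start": starts, "end": ends,
        "name": [f"read{j:07d}" for j in range(len(starts))],
    })
    track = DepthTrack.from_reads(reads, regions.targets)
    return (reads if emit_reads else None), track


# -- call sets ----------------------------------------------------------------

def _draw_family(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "lognormal":
        return rng.lognormal(spec[1], spec[2], size=n)
    if kind == "beta":
        return rng.beta(spec[1], spec[2], size=n)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    if kind == "poisson":
        return rng.poisson(spec[1], size=n) + spec[2]
    if kind == "stb_balanced":      # balanced strands, small half-normal skew
        return np.clip(0.5 + np.abs(rng.normal(0.0, spec[1], size=n)), 0.5, 1.0)
    if kind == "stb_skewed":        # pushed toward one-sided (1.0)
        return 0.5 + 0.5 * rng.beta(spec[1], spec[2], size=n)
    raise ValueError(f"unknown distribution family {kind!r}")


def _draw_annotations(cfg: SimConfig, rng: np.random.Generator, label: str,
                      vclass: str, depths: np.ndarray) -> pd.DataFrame:
    """Draw the 11-parameter annotation block for n calls of one label/class."""
    m = cfg.annotation_model
    n = len(depths)
    dp = np.maximum(np.asarray(depths, dtype=int), 1)
    fdp = np.maximum(np.round(_draw_family(rng, m["FDP_fraction"], n) * dp), 1)
    if label == "tp":
        fao = np.maximum(np.round(_draw_family(rng, m["FAO_fraction_tp"], n) * fdp), 1)
    else:
        fao = np.minimum(_draw_family(rng, m["FAO_fp"], n), fdp)
        fao = np.maximum(fao, 1)
    ao = np.minimum(np.maximum(np.round(fao * _draw_family(rng, m["AO_jitter"], n)), 1), dp)
    qual = _draw_family(rng, m["QUAL"][label], n)
    hrun_key = "HRUN_indel" if vclass == "indel" else "HRUN_snp"
    return pd.DataFrame({
        "AO": ao.astype(int), "DP": dp.astype(int),
        "FAO": fao.astype(int), "FDP": fdp.astype(int),
        "FXX": _draw_family(rng, m["FXX"][label], n),
        "GQ": np.maximum(np.round(_draw_family(rng, m["GQ"][label], n)), 1).astype(int),
        "HRUN": _draw_family(rng, m[hrun_key][label], n).astype(int),
        "QUAL": qual,
        "QD": qual / dp,
        "STB": _draw_family(rng, m["STB"][label], n),
        "STBP": _draw_family(rng, m["STBP"][label], n),
    })


@dataclass
class _FpTemplate:
    """One cohort-level false-positive variant (possibly multiallelic)."""

    vclass: str                       # "snp" | "indel"
    record_pos: int                   # 1-based VCF position
    ref: str
    alts: List[str]
    norm_keys: List[Tuple[str, int, str, str]]
    norm_variants: List[NormalizedVariant]
    samples: List[int]                # sample indices carrying this FP


def _make_fp_templates(cfg: SimConfig, reference: Mapping[str, str],
                       regions: RegionBundle,
                       truth_keys: set) -> List[_FpTemplate]:
    """Plan the cohort's false-positive variants.

    Each distinct FP is private to one sample with probability
    ``fp_unique_fraction``, otherwise shared by k ~ Uniform{2..n_samples}
    samples, so the expected fraction of distinct FPs seen in exactly one
    sample equals the configured uniqueness.  The planned count is chosen so
    the expected per-sample FP load matches ``fp_per_sample_*``.
    """
    rng = cfg.rng(_STREAM_FP_PLAN)
    seq = reference[CHROM]
    ev = regions.evaluation
    S = cfg.n_samples
    templates: List[_FpTemplate] = []
    used_keys = set(truth_keys)
    used_sites = set()

    plan = []
    for vclass, per_sample in (("snp", cfg.fp_per_sample_snp),
                               ("indel", cfg.fp_per_sample_indel)):
        if per_sample == 0:
            continue
        if S == 1:
            n_distinct = per_sample
        else:
            ek = (2 + S) / 2.0
            fpu = cfg.fp_unique_fraction
            n_distinct = max(1, round(S * per_sample / (fpu + (1 - fpu) * ek)))
        plan.append((vclass, n_distinct))
    total = sum(n for _, n in plan)
    if total == 0:
        return []
    spare = max(256, total // 5)
    positions = iter(_draw_positions(cfg, regions, rng, total + spare))

    for vclass, n_distinct in plan:
        for _ in range(n_distinct):
            made = None
            for _attempt in range(300):
                try:
                    pos0 = int(next(positions))
                except StopIteration:
                    raise ValueError("exhausted candidate positions for FP plan")
                if pos0 in used_sites:
                    continue
                multi = (vclass == "indel"
                         and rng.random() < cfg.multiallelic_fp_indel_fraction)
                if vclass == "snp":
                    pos, ref, alt = _make_snp(seq, pos0, rng)
                    alts = [alt]
                elif not multi:
                    pos, ref, alt = _make_indel(seq, pos0, rng)
                    alts = [alt]
                else:
                    # three alternate alleles of different lengths at one site
                    pos = pos0 + 1
                    ref = seq[pos0:pos0 + 3]
                    ins = str(rng.choice(list("ACGT")))
                    alts = [seq[pos0], seq[pos0:pos0 + 2], ref + ins]
                try:
                    rec = VariantRecord(CHROM, pos, ref, list(alts), qual=10.0)
                except ValueError:
                    continue
                norm = [left_align(r, reference) for r in split_multiallelic(rec)]
                keys = [v.key for v in norm]
                if len(set(keys)) != len(keys):
                    continue
                if any(k in used_keys for k in keys):
                    continue
                if not all(ev.contains(CHROM, v.pos - 1) for v in norm):
                    continue
                made = (pos, ref, alts, keys, norm)
                break
            if made is None:
                raise ValueError("could not place a false-positive variant")
            pos, ref, alts, keys, norm = made
            used_keys.update(keys)
            used_sites.add(pos - 1)
            if S == 1:
                samples = [0]
            elif rng.random() < cfg.fp_unique_fraction:
                samples = [int(rng.integers(S))]
            else:
                k = int(rng.integers(2, S + 1))
                samples = sorted(int(x) for x in
                                 rng.choice(S, size=k, replace=False))
            templates.append(_FpTemplate(
                vclass=vclass, record_pos=pos, ref=ref, alts=list(alts),
                norm_keys=keys, norm_variants=norm, samples=samples))
    return templates


@dataclass
class SyntheticCallset:
    """One sample's emitted call set with its exact label bookkeeping."""

    sample_id: str
    records: List[VariantRecord]          # VCF-level (may be multiallelic)
    labels: pd.DataFrame                  # normalized-level TP/FP rows
    fn: pd.DataFrame                      # missed truth variants + site depth


def _truth_class(v: NormalizedVariant) -> str:
    return "indel" if v.is_indel else "snp"


def make_callset(cfg: SimConfig, truth: Sequence[NormalizedVariant],
                 depth: DepthTrack, sample_index: int,
                 reference: Mapping[str, str],
                 fp_templates: Optional[Sequence[_FpTemplate]] = None,
                 sample_id: Optional[str] = None) -> SyntheticCallset:
    """Emit one annotated call set: truth minus depth-structured FN, plus
    the sample's share of the cohort FP plan, all with class-conditional
    annotation draws."""
    rng = cfg.rng(_STREAM_SAMPLE_BASE + sample_index, 1)
    sample_id = sample_id or f"S{sample_index:02d}"

    positions = np.array([v.pos - 1 for v in truth])
    site_depth = np.nan_to_num(depth.values_at(CHROM, positions), nan=0.0)
    is_indel = np.array([v.is_indel for v in truth])
    low = site_depth < 10

    fn_mask = np.zeros(len(truth), dtype=bool)
    for vclass, fn_rate, f_low in (
            ("snp", cfg.fn_rate_snp, cfg.low_depth_fn_fraction),
            ("indel", cfg.fn_rate_indel, cfg.low_depth_fn_fraction_indel)):
        cls = is_indel if vclass == "indel" else ~is_indel
        n_cls = int(cls.sum())
        if n_cls == 0 or fn_rate == 0:
            continue
        w = float((cls & low).sum()) / n_cls
        p_low_target = f_low * fn_rate / w if w > 0 else 0.0
        p_low = min(1.0, p_low_target)
        if p_low < p_low_target:
            warnings.warn(
                f"{vclass}: too few low-depth truth sites (fraction {w:.3f}) "
                f"to place {f_low:.0%} of FN at depth<10; clamping")
        p_high = (fn_rate - p_low * w) / (1 - w) if w < 1 else 0.0
        p_high = min(max(p_high, 0.0), 1.0)
        u = rng.random(len(truth))
        fn_mask |= cls & np.where(low, u < p_low, u < p_high)

    tp_idx = np.flatnonzero(~fn_mask)
    fn_idx = np.flatnonzero(fn_mask)

    label_rows: List[dict] = []
    records: List[VariantRecord] = []

    for vclass in ("snp", "indel"):
        cls = np.fromiter((_truth_class(truth[i]) == vclass for i in tp_idx),
                          dtype=bool, count=len(tp_idx))
        idx = tp_idx[cls] if len(tp_idx) else tp_idx
        if not len(idx):
            continue
        ann = _draw_annotations(cfg, rng, "tp", vclass, site_depth[idx])
        for row_i, i in enumerate(idx):
            v = truth[i]
            a = ann.iloc[row_i]
            annotations = {k: (int(a[k]) if k in ("AO", "DP", "FAO", "FDP",
                                                  "GQ", "HRUN") else float(a[k]))
                           for k in ("AO", "DP", "FAO", "FDP", "FXX", "GQ",
                                     "HRUN", "QD", "STB", "STBP")}
            rec_ann = dict(annotations)
            rec_ann["AO"] = [annotations["AO"]]
            rec_ann["FAO"] = [annotations["FAO"]]
            records.append(VariantRecord(
                v.chrom, v.pos, v.ref, [v.alt], qual=float(a["QUAL"]),
                annotations=rec_ann))
            label_rows.append({
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "record_pos": v.pos,
                "variant_class": vclass, "label": "tp",
                "n_original_alts": 1, "indel_length": v.indel_length,
                "QUAL": float(a["QUAL"]), **annotations,
            })

    if fp_templates is None:
        truth_keys = {v.key for v in truth}
        # single-sample convenience: plan FPs on the fly
        one = SimConfig(**{**cfg.__dict__, "n_samples": 1}) \
            if cfg.n_samples != 1 else cfg
        regions = make_region_sets(cfg)
        fp_templates = _make_fp_templates(one, reference, regions, truth_keys)
        for t in fp_templates:
            t.samples = [sample_index]

    mine = [t for t in fp_templates if sample_index in t.samples]
    for vclass in ("snp", "indel"):
        tmpl = [t for t in mine if t.vclass == vclass]
        if not tmpl:
            continue
        d = np.nan_to_num(depth.values_at(
            CHROM, np.array([t.record_pos - 1 for t in tmpl])), nan=0.0)
        ann = _draw_annotations(cfg, rng, "fp", vclass, d)
        for row_i, t in enumerate(tmpl):
            a = ann.iloc[row_i]
            k = len(t.alts)
            site_ann = {key: (int(a[key]) if key in ("DP", "FDP", "GQ", "HRUN")
                              else float(a[key]))
                        for key in ("DP", "FDP", "FXX", "GQ", "HRUN", "QD",
                                    "STB", "STBP")}
            # per-allele observations: split the drawn FAO across alleles
            fao_total = int(a["FAO"])
            per_alt_fao = [max(1, fao_total // k)] * k
            per_alt_ao = [max(1, int(round(f * float(
                np.clip(a["AO"] / max(a["FAO"], 1), 0.8, 1.2)))))
                for f in per_alt_fao]
            rec_ann = dict(site_ann)
            rec_ann["AO"] = per_alt_ao
            rec_ann["FAO"] = per_alt_fao
            records.append(VariantRecord(
                CHROM, t.record_pos, t.ref, list(t.alts),
                qual=float(a["QUAL"]), annotations=rec_ann))
            for alt_i, v in enumerate(t.norm_variants):
                label_rows.append({
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "record_pos": t.record_pos,
                    "variant_class": vclass, "label": "fp",
                    "n_original_alts": k, "indel_length": v.indel_length,
                    "QUAL": float(a["QUAL"]),
                    "AO": per_alt_ao[alt_i], "DP": site_ann["DP"],
                    "FAO": per_alt_fao[alt_i], "FDP": site_ann["FDP"],
                    "FXX": site_ann["FXX"], "GQ": site_ann["GQ"],
                    "HRUN": site_ann["HRUN"], "QD": site_ann["QD"],
                    "STB": site_ann["STB"], "STBP": site_ann["STBP"],
                })

    fn_rows = [{
        "chrom": truth[i].chrom, "pos": truth[i].pos,
        "ref": truth[i].ref, "alt": truth[i].alt,
        "variant_class": _truth_class(truth[i]),
        "site_depth": float(site_depth[i]),
        "low_depth": bool(site_depth[i] < 10),
    } for i in fn_idx]

    label_cols = ["chrom", "pos", "ref", "alt", "record_pos",
                  "variant_class", "label",
                  "n_original_alts", "indel_length", "AO", "DP", "FAO",
                  "FDP", "FXX", "GQ", "HRUN", "QD", "QUAL", "STB", "STBP"]
    labels = pd.DataFrame(label_rows, columns=label_cols)
    labels["sample"] = sample_id
    fn = pd.DataFrame(fn_rows, columns=["chrom", "pos", "ref", "alt",
                                        "variant_class", "site_depth",
                                        "low_depth"])
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alts[0]))
    return SyntheticCallset(sample_id=sample_id, records=records,
                            labels=labels, fn=fn)


# -- cohort driver ------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A complete synthetic study: reference, regions, truth, per-sample
    call sets, depth tracks and (optionally) read placements — plus file
    paths when written to disk."""

    config: SimConfig
    reference: Dict[str, str]
    regions: RegionBundle
    truth: List[NormalizedVariant]
    callsets: Dict[str, SyntheticCallset]
    depth: Dict[str, DepthTrack]
    reads: Dict[str, Optional[pd.DataFrame]]
    fp_templates: List[_FpTemplate]
    paths: Dict[str, object] = field(default_factory=dict)

    @property
    def labels(self) -> pd.DataFrame:
        """Pooled per-sample label table (the tuning training frame)."""
        return pd.concat([cs.labels for cs in self.callsets.values()],
                         ignore_index=True)


def simulate_cohort(cfg: SimConfig, outdir: Optional[Path] = None,
                    emit_reads: bool = True) -> SyntheticCohort:
    """Generate a full cohort; write all artifacts under ``outdir`` if given.

    Files written: reference FASTA, region BEDs (targets, cds,
    high_confidence, amplicons), truth VCF, per-sample call VCFs, per-sample
    bedGraph depth, per-sample read BEDs and a sidecar label table (TSV).
    """
    reference, _ = make_reference(cfg)
    regions = make_region_sets(cfg)
    truth = make_truth_variants(cfg, reference, regions)
    truth_keys = {v.key for v in truth}
    fp_templates = _make_fp_templates(cfg, reference, regions, truth_keys)

    weights = amplicon_weights(cfg, regions)
    callsets: Dict[str, SyntheticCallset] = {}
    depth: Dict[str, DepthTrack] = {}
    reads: Dict[str, Optional[pd.DataFrame]] = {}
    for i in range(cfg.n_samples):
        sid = f"S{i:02d}"
        rd, track = make_depth_and_reads(cfg, regions, i, weights=weights,
                                         emit_reads=emit_reads)
        depth[sid] = track
        reads[sid] = rd
        callsets[sid] = make_callset(cfg, truth, track, i, reference,
                                     fp_templates=fp_templates, sample_id=sid)

    cohort = SyntheticCohort(
        config=cfg, reference=reference, regions=regions, truth=truth,
        callsets=callsets, depth=depth, reads=reads,
        fp_templates=fp_templates)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        contigs = {c: len(s) for c, s in reference.items()}
        paths: Dict[str, object] = {}
        paths["reference"] = outdir / "reference.fa"
        write_fasta(reference, paths["reference"])
        for name, iset in (("targets", regions.targets), ("cds", regions.cds),
                           ("high_confidence", regions.high_confidence)):
            paths[name] = outdir / f"{name}.bed"
            write_bed(iset, paths[name])
        paths["amplicons"] = outdir / "amplicons.bed"
        write_bed_records(regions.amplicons, paths["amplicons"])
        paths["exons"] = outdir / "exons.bed"
        write_bed_records(regions.exons, paths["exons"])
        paths["truth"] = outdir / "truth.vcf"
        write_vcf(truth, paths["truth"], contigs, sample_name="TRUTH")
        paths["callsets"] = {}
        paths["depth"] = {}
        paths["reads"] = {}
        for sid, cs in callsets.items():
            p = outdir / f"{sid}.vcf"
            write_vcf(cs.records, p, contigs, sample_name=sid)
            paths["callsets"][sid] = p
            pd_path = outdir / f"{sid}.bedgraph"
            depth[sid].to_bedgraph(pd_path)
            paths["depth"][sid] = pd_path
            if reads[sid] is not None:
                rp = outdir / f"{sid}.reads.bed"
                write_bed_records(
                    list(reads[sid][["chrom", "start", "end", "name"]]
                         .itertuples(index=False, name=None)), rp)
                paths["reads"][sid] = rp
        paths["labels"] = outdir / "labels.tsv"
        cohort.labels.to_csv(paths["labels"], sep="\t", index=False)
        cohort.paths = paths
    return cohort
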