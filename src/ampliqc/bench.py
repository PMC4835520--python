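"""Truth-set benchmarking of normalized call sets.

Calls are compared to a gold-standard truth set by exact key — identical
(chrom, pos, ref, alt) after normalization — separately for SNPs and indels.
Genotype/zygosity is deliberately ignored: concordance is allele-level.
Error characterization covers multiallelic origin, indel length classes,
low-depth false negatives and cross-sample recurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .vcfnorm import NormalizedVariant

__all__ = [
    "BenchmarkResult",
    "ErrorProfile",
    "match_to_truth",
    "accuracy_stats",
    "recurrence_profile",
    "error_profile",
    "calls_to_frame",
]

Key = Tuple[str, int, str, str]

#: Indel length classes used in the length histograms.
INDEL_LENGTH_CLASSES = (("1-2bp", 1, 2), ("3-100bp", 3, 100), (">100bp", 101, None))

#: Sites with fewer reads than this are "low depth" for FN accounting.
LOW_DEPTH_THRESHOLD = 10


def _class_of(v: NormalizedVariant) -> str:
    """Benchmark class: 'snp', 'indel', or 'complex' (excluded from both)."""
    if v.is_indel:
        return "indel"
    if len(v.ref) == 1 and len(v.alt) == 1:
        return "snp"
    return "complex"


def _filter_class(variants: Sequence[NormalizedVariant], variant_class: str
                  ) -> List[NormalizedVariant]:
    if variant_class not in ("snp", "indel"):
        raise ValueError("variant_class must be 'snp' or 'indel'")
    return [v for v in variants if _class_of(v) == variant_class]


@dataclass
class BenchmarkResult:
    """TP/FP/FN partition of one call set against the truth, for one class."""

    variant_class: str
    tp: List[NormalizedVariant]
    fp: List[NormalizedVariant]
    fn: List[NormalizedVariant]

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)

    @property
    def sensitivity(self) -> float:
        denom = self.n_tp + self.n_fn
        if denom == 0:
            raise ValueError("empty truth set in evaluated region")
        return self.n_tp / denom

    @property
    def precision(self) -> float:
        denom = self.n_tp + self.n_fp
        if denom == 0:
            warnings.warn("no calls made; precision reported as 1.0 by convention")
            return 1.0
        return self.n_tp / denom

    @property
    def fdr(self) -> float:
        return 1.0 - self.precision

    @property
    def f1(self) -> float:
        p, s = self.precision, self.sensitivity
        if p + s == 0:
            return 0.0
        if self.n_tp == 0:
            return 0.0
        return 2 * p * s / (p + s)


def match_to_truth(calls: Sequence[NormalizedVariant],
                   truth: Sequence[NormalizedVariant],
                   variant_class: str) -> BenchmarkResult:
    """Partition calls into TP/FP and truth into matched/FN by exact key.

    Both inputs must be normalized (single-alt, left-aligned) and already
    restricted to the evaluation region; the class filter (``snp`` or
    ``indel``) is applied to both sides here, so SNPs and indels are
    evaluated separately.
    """
    for v in calls:
        if "," in v.alt:
            raise ValueError("un-normalized multiallelic record in calls")
    calls_c = _filter_class(calls, variant_class)
    truth_c = _filter_class(truth, variant_class)
    truth_keys = {v.key for v in truth_c}
    call_keys = {v.key for v in calls_c}
    tp = [v for v in calls_c if v.key in truth_keys]
    fp = [v for v in calls_c if v.key not in truth_keys]
    fn = [v for v in truth_c if v.key not in call_keys]
    return BenchmarkResult(variant_class=variant_class, tp=tp, fp=fp, fn=fn)


def accuracy_stats(result: BenchmarkResult) -> Dict[str, float]:
    """Sensitivity, precision, FDR and F1 for a benchmark partition."""
    return {
        "n_tp": result.n_tp,
        "n_fp": result.n_fp,
        "n_fn": result.n_fn,
        "sensitivity": result.sensitivity,
        "precision": result.precision,
        "fdr": result.fdr,
        "f1": result.f1,
    }


def recurrence_profile(per_sample: Mapping[str, Mapping[str, Sequence[NormalizedVariant]]]
                       ) -> Dict[str, object]:
    """Cross-sample recurrence of TP and FP variants.

    ``per_sample`` maps sample id -> {"tp": [...], "fp": [...]}.  For each
    distinct variant key the number of samples containing it is counted,
    separately per label.  The summary exposes the fraction of distinct TP
    present in at least n_samples - 1 samples and the fraction of distinct FP
    private to a single sample.
    """
    samples = list(per_sample)
    if len(samples) < 2:
        raise ValueError("recurrence analysis requires >= 2 samples")
    n_samples = len(samples)
    counts: Dict[str, Dict[Key, int]] = {"tp": {}, "fp": {}}
    for sid in samples:
        for label in ("tp", "fp"):
            for v in per_sample[sid].get(label, []):
                counts[label][v.key] = counts[label].get(v.key, 0) + 1
    # a key seen as TP in one sample and FP in another means the per-sample
    # truth sets disagree
    both = set(counts["tp"]) & set(counts["fp"])
    if both:
        raise ValueError(f"{len(both)} keys labelled TP in one sample and FP "
                         "in another: inconsistent truth sets")
    hist = {}
    for label in ("tp", "fp"):
        h = np.zeros(n_samples + 1, dtype=int)
        for c in counts[label].values():
            h[c] += 1
        hist[label] = h
    n_tp_distinct = int(hist["tp"].sum())
    n_fp_distinct = int(hist["fp"].sum())
    return {
        "n_samples": n_samples,
        "histogram_tp": hist["tp"],
        "histogram_fp": hist["fp"],
        "n_tp_distinct": n_tp_distinct,
        "n_fp_distinct": n_fp_distinct,
        "tp_fraction_recurrent": (hist["tp"][n_samples - 1:].sum() / n_tp_distinct
                                  if n_tp_distinct else float("nan")),
        "fp_fraction_unique": (hist["fp"][1] / n_fp_distinct
                               if n_fp_distinct else float("nan")),
    }


@dataclass
class ErrorProfile:
    """Characterization of benchmarking errors for one sample/class."""

    multiallelic_ge2_fp: float
    multiallelic_ge3_fp: float
    multiallelic_ge2_tp: float
    multiallelic_ge3_tp: float
    indel_length_hist: pd.DataFrame
    fn_low_depth_fraction: float
    fn_depth_unknown: int
    site_counts: Dict[str, int] = field(default_factory=dict)


def _multiallelic_fractions(variants: Sequence[NormalizedVariant]
                            ) -> Tuple[float, float, int]:
    """Fractions of distinct original call records with >=2 / >=3 alternate
    alleles.  Split siblings of one multiallelic record are collapsed onto
    their originating record (via ``source_pos`` where available) so a
    3-alt VCF line counts once, as in the source file."""
    sites: Dict[Tuple[str, int], int] = {}
    for v in variants:
        site = (v.chrom, v.source_pos if v.source_pos is not None else v.pos)
        sites[site] = max(sites.get(site, 0), v.n_original_alts)
    n = len(sites)
    if n == 0:
        return 0.0, 0.0, 0
    ge2 = sum(1 for k in sites.values() if k >= 2)
    ge3 = sum(1 for k in sites.values() if k >= 3)
    return ge2 / n, ge3 / n, n


def _indel_length_class(length: int) -> Optional[str]:
    for name, lo, hi in INDEL_LENGTH_CLASSES:
        if length >= lo and (hi is None or length <= hi):
            return name
    return None


def error_profile(result: BenchmarkResult, depth=None) -> ErrorProfile:
    """Profile the errors of one benchmark partition.

    ``depth`` is a :class:`~ampliqc.covstats.DepthTrack` (or None); FN sites
    with no depth information are counted separately as unknown, not folded
    into the low-depth fraction.
    """
    ge2_fp, ge3_fp, n_fp_sites = _multiallelic_fractions(result.fp)
    ge2_tp, ge3_tp, n_tp_sites = _multiallelic_fractions(result.tp)

    rows = []
    for label, variants in (("tp", result.tp), ("fp", result.fp), ("fn", result.fn)):
        counts = {name: 0 for name, *_ in INDEL_LENGTH_CLASSES}
        for v in variants:
            if v.is_indel:
                counts[_indel_length_class(v.indel_length)] += 1
        rows.append({"label": label, **counts})
    length_hist = pd.DataFrame(rows).set_index("label")

    n_low = 0
    n_known = 0
    n_unknown = 0
    for v in result.fn:
        d = None if depth is None else depth.value_at(v.chrom, v.pos - 1)
        if d is None:
            n_unknown += 1
        else:
            n_known += 1
            if d < LOW_DEPTH_THRESHOLD:
                n_low += 1
    fn_low = n_low / n_known if n_known else float("nan")

    return ErrorProfile(
        multiallelic_ge2_fp=ge2_fp, multiallelic_ge3_fp=ge3_fp,
        multiallelic_ge2_tp=ge2_tp, multiallelic_ge3_tp=ge3_tp,
        indel_length_hist=length_hist,
        fn_low_depth_fraction=fn_low, fn_depth_unknown=n_unknown,
        site_counts={"fp_sites": n_fp_sites, "tp_sites": n_tp_sites},
    )


def calls_to_frame(variants: Sequence[NormalizedVariant],
                   label: Optional[str] = None,
                   sample: Optional[str] = None) -> pd.DataFrame:
    """Flatten normalized variants into a DataFrame with the 11 caller
    parameters as columns (missing values become NaN), ready for parameter
    profiling and threshold tuning."""
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "variant_class": _class_of(v), "QUAL": float(v.qual),
            "n_original_alts": v.n_original_alts,
            "indel_length": v.indel_length,
        }
        for key in ("AO", "DP", "FAO", "FDP", "FXX", "GQ", "HRUN", "QD", "STB", "STBP"):
            val = v.annotations.get(key)
            row[key] = float(val) if val is not None else np.nan
        if label is not None:
            row["label"] = label
        if sample is not None:
            row["sample"] = sample
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "variant_class", "n_original_alts",
            "indel_length", "AO", "DP", "FAO", "FDP", "FXX", "GQ", "HRUN",
            "QD", "QUAL", "STB", "STBP"]
    if label is not None:
        cols.append("label")
    if sample is not None:
        cols.append("sample")
    return pd.DataFrame(rows, columns=cols)
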