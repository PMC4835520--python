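"""VCF record model and normalization.

Implements the call-set normalization used throughout the benchmark:
multiallelic sites are split into one record per alternate allele (carrying
the original allele count along as ``N_ORIG_ALTS``), indels are left-aligned
against the reference to their left-most minimal representation, and records
are restricted to an evaluation region set.

Records carry the annotation block emitted by flow-space variant callers on
semiconductor sequencers: AO (alternate allele observations), DP (read
depth), FAO/FDP (their flow-space analogues), FXX (flow evaluator failed
read ratio), GQ (genotype quality), HRUN (reference homopolymer length at
the site), QD (quality per read depth), STB (strand bias ratio, 0.5 =
balanced), STBP (strand bias p value), plus the QUAL column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pysam

from .regions import IntervalSet

__all__ = [
    "ANNOTATION_KEYS",
    "PER_ALLELE_KEYS",
    "VariantRecord",
    "NormalizedVariant",
    "split_multiallelic",
    "left_align",
    "normalize_records",
    "restrict_to_regions",
    "read_vcf",
    "write_vcf",
]

#: The 11 caller parameters profiled by the benchmark (QUAL lives in the VCF
#: QUAL column; the other 10 in INFO/FORMAT).
ANNOTATION_KEYS = ("AO", "DP", "FAO", "FDP", "FXX", "GQ", "HRUN", "QD", "STB", "STBP")

#: Annotations with one value per alternate allele.
PER_ALLELE_KEYS = ("AO", "FAO")

_VALID_BASES = frozenset("ACGTN")


class ReferenceMismatchError(ValueError):
    """Raised when a record's REF allele disagrees with the reference."""


@dataclass
class VariantRecord:
    """One VCF entry (possibly multiallelic) with its annotation block."""

    chrom: str
    pos: int                      # 1-based, VCF convention
    ref: str
    alts: List[str]
    qual: float = 0.0
    annotations: Dict[str, object] = field(default_factory=dict)
    n_original_alts: Optional[int] = None
    filter: str = "."
    flags: List[str] = field(default_factory=list)   # e.g. missing annotations

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if not self.alts:
            raise ValueError("record must carry at least one alternate allele")
        for allele in [self.ref, *self.alts]:
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"invalid allele {allele!r}")
        for key in PER_ALLELE_KEYS:
            if key in self.annotations:
                vals = self.annotations[key]
                if not isinstance(vals, (list, tuple)) or len(vals) != len(self.alts):
                    raise ValueError(f"{key} must carry one value per alt")
        if self.n_original_alts is None:
            self.n_original_alts = len(self.alts)


@dataclass
class NormalizedVariant:
    """A single-alt, left-aligned, minimally represented variant."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    qual: float = 0.0
    annotations: Dict[str, object] = field(default_factory=dict)
    n_original_alts: int = 1
    filter: str = "."
    flags: List[str] = field(default_factory=list)
    #: POS of the originating VCF record (before splitting/left-alignment);
    #: lets split siblings of one multiallelic line be grouped back together
    source_pos: Optional[int] = None

    @property
    def variant_class(self) -> str:
        """"snp", "insertion", "deletion" or "complex" (equal-length MNP)."""
        lr, la = len(self.ref), len(self.alt)
        if lr == la == 1:
            return "snp"
        if lr < la:
            return "insertion"
        if lr > la:
            return "deletion"
        return "complex"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """Exact-match key (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


Reference = Union[Mapping[str, str], "pysam.FastaFile", object]


def _ref_slice(reference: Reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch reference bases [start0, end0), 0-based, from a dict of strings,
    a pyfaidx.Fasta or a pysam.FastaFile."""
    seq = reference[chrom] if not hasattr(reference, "fetch") else None
    if seq is not None:
        return str(seq[start0:end0]).upper()
    return reference.fetch(chrom, start0, end0).upper()


def split_multiallelic(rec: VariantRecord) -> List[VariantRecord]:
    """Split a record into one record per alternate allele.

    Per-allele annotations (AO, FAO) are routed to the record of the matching
    allele; site-level annotations are copied.  Every output record carries
    ``n_original_alts`` equal to the original alternate-allele count.
    """
    k = len(rec.alts)
    out = []
    for i, alt in enumerate(rec.alts):
        ann: Dict[str, object] = {}
        for key, val in rec.annotations.items():
            if key in PER_ALLELE_KEYS:
                ann[key] = [val[i]]
            else:
                ann[key] = val
        out.append(VariantRecord(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=[alt],
            qual=rec.qual, annotations=ann, n_original_alts=k,
            filter=rec.filter, flags=list(rec.flags),
        ))
    return out


def left_align(rec: VariantRecord, reference: Reference) -> NormalizedVariant:
    """Normalize a single-alt record to its left-most minimal representation.

    The result is haplotype-equivalent to the input: applying either edit to
    the reference yields the same sequence.  Indels keep one anchor base (the
    standard VCF convention); when trimming would empty an allele, both
    alleles are extended to the left with the reference base and the position
    shifted down, which walks the indel to its left-most placement.
    """
    if len(rec.alts) != 1:
        raise ValueError("left_align requires a single-alt record; split first")
    chrom, pos, ref, alt = rec.chrom, rec.pos, rec.ref, rec.alts[0]

    observed = _ref_slice(reference, chrom, pos - 1, pos - 1 + len(ref))
    if observed != ref.upper():
        raise ReferenceMismatchError(
            f"{chrom}:{pos} REF {ref!r} disagrees with reference {observed!r}")
    ref, alt = ref.upper(), alt.upper()

    # Trim shared trailing bases; extend left when an allele would empty.
    while ref[-1] == alt[-1] and (ref != alt):
        if len(ref) == 1 or len(alt) == 1:
            if pos == 1:
                break
            base = _ref_slice(reference, chrom, pos - 2, pos - 1)
            ref = base + ref[:-1]
            alt = base + alt[:-1]
            pos -= 1
        else:
            ref = ref[:-1]
            alt = alt[:-1]
    # Trim shared leading bases beyond the single anchor.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1

    ann = dict(rec.annotations)
    for key in PER_ALLELE_KEYS:
        if key in ann:
            ann[key] = ann[key][0]
    return NormalizedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=rec.qual,
        annotations=ann, n_original_alts=rec.n_original_alts or 1,
        filter=rec.filter, flags=list(rec.flags), source_pos=rec.pos,
    )


def normalize_records(records: Iterable[VariantRecord],
                      reference: Reference) -> List[NormalizedVariant]:
    """Split multiallelic records and left-align every resulting allele."""
    out = []
    for rec in records:
        for single in split_multiallelic(rec):
            out.append(left_align(single, reference))
    return out


def restrict_to_regions(variants: Sequence[NormalizedVariant],
                        regions: IntervalSet) -> List[NormalizedVariant]:
    """Keep variants whose POS (converted to 0-based) lies inside ``regions``.

    Membership is judged on the normalized position only, not the full REF
    span, so boundary indels are handled deterministically.
    """
    return [v for v in variants if regions.contains(v.chrom, v.pos - 1)]


# -- VCF I/O ------------------------------------------------------------------

_INFO_DEFS = [
    ("AO", "A", "Integer", "Alternate allele observations"),
    ("DP", "1", "Integer", "Read depth at the site"),
    ("FAO", "A", "Integer", "Flow-space alternate allele observations"),
    ("FDP", "1", "Integer", "Flow-space read depth"),
    ("FXX", "1", "Float", "Flow evaluator failed read ratio"),
    ("HRUN", "1", "Integer", "Reference homopolymer run length at the site"),
    ("QD", "1", "Float", "Variant quality per read depth"),
    ("STB", "1", "Float", "Strand bias ratio (0.5 = balanced)"),
    ("STBP", "1", "Float", "Strand bias p value"),
    ("N_ORIG_ALTS", "1", "Integer", "Alternate allele count before splitting"),
]


def _fmt(v: object) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_vcf(records: Sequence[Union[VariantRecord, NormalizedVariant]],
              path, contigs: Mapping[str, int],
              sample_name: str = "SAMPLE",
              write_n_orig_alts: bool = False,
              filter_defs: Sequence[str] = ()) -> None:
    """Write records as plain-text VCF 4.2 (sorted by chrom, pos)."""
    lines = []
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
        if isinstance(rec, NormalizedVariant):
            alts = [rec.alt]
            per_allele = {k: [rec.annotations[k]] for k in PER_ALLELE_KEYS
                          if k in rec.annotations}
        else:
            alts = rec.alts
            per_allele = {k: rec.annotations[k] for k in PER_ALLELE_KEYS
                          if k in rec.annotations}
        info_parts = []
        for key, *_ in _INFO_DEFS:
            if key == "N_ORIG_ALTS":
                if write_n_orig_alts:
                    info_parts.append(f"N_ORIG_ALTS={rec.n_original_alts}")
                continue
            if key in per_allele:
                info_parts.append(f"{key}=" + ",".join(_fmt(v) for v in per_allele[key]))
            elif key in rec.annotations and key != "GQ":
                info_parts.append(f"{key}={_fmt(rec.annotations[key])}")
        info = ";".join(info_parts) if info_parts else "."
        gq = rec.annotations.get("GQ")
        fmt_col = "GT:GQ"
        sample_col = f"0/1:{_fmt(gq)}" if gq is not None else "0/1:."
        filt = rec.filter if rec.filter and rec.filter != "." else "."
        lines.append("\t".join([
            rec.chrom, str(rec.pos), ".", rec.ref, ",".join(alts),
            _fmt(float(rec.qual)), filt, info, fmt_col, sample_col,
        ]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for name in filter_defs:
            fh.write(f'##FILTER=<ID={name},Description="{name}">\n')
        for key, num, typ, desc in _INFO_DEFS:
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


def read_vcf(path) -> List[VariantRecord]:
    """Read a VCF into VariantRecords.

    Annotations listed in :data:`ANNOTATION_KEYS` are collected from INFO
    (GQ from the first sample's FORMAT).  Records missing annotations are
    passed through with a flag per missing key, never dropped.
    """
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ann: Dict[str, object] = {}
            flags: List[str] = []
            for key in ANNOTATION_KEYS:
                if key == "GQ":
                    continue
                if key in rec.info:
                    val = rec.info[key]
                    if key in PER_ALLELE_KEYS:
                        ann[key] = list(val) if isinstance(val, tuple) else [val]
                    else:
                        val = val[0] if isinstance(val, tuple) else val
                        ann[key] = float(val) if isinstance(val, float) else val
                else:
                    flags.append(f"missing:{key}")
            if rec.samples and "GQ" in rec.samples[0]:
                gq = rec.samples[0]["GQ"]
                if gq is not None:
                    ann["GQ"] = int(gq)
                else:
                    flags.append("missing:GQ")
            else:
                flags.append("missing:GQ")
            n_orig = (rec.info["N_ORIG_ALTS"]
                      if "N_ORIG_ALTS" in rec.info else None)
            if isinstance(n_orig, tuple):
                n_orig = n_orig[0]
            out.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alts=list(rec.alts or []),
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                annotations=ann,
                n_original_alts=int(n_orig) if n_orig is not None else None,
                filter=";".join(rec.filter.keys()) or ".",
                flags=flags,
            ))
    return out
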