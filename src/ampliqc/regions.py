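"""Interval algebra over BED-style genomic region sets.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``,
strand-free.  VCF positions (1-based) are converted at module boundaries.
Region sets are kept canonical (sorted, merged, non-overlapping) so that
set operations and base counting are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "kit_gene_coverage",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-free genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A canonical set of genomic intervals.

    Canonical form: per chromosome, intervals are sorted by start and merged so
    that no two intervals overlap or touch (book-ended intervals ``[a,b)`` and
    ``[b,c)`` merge to ``[a,c)``).  Internally each chromosome holds two numpy
    arrays (starts, ends) to keep membership queries and sweeps vectorised.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(per_chrom):
            spans = sorted(per_chrom[chrom])
            merged: List[List[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self._data[chrom] = (starts, ends)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_spans(cls, chrom: str, spans: Iterable[Tuple[int, int]]) -> "IntervalSet":
        return cls(GenomicInterval(chrom, s, e) for s, e in spans)

    @classmethod
    def _from_arrays(cls, data: Mapping[str, Tuple[np.ndarray, np.ndarray]]) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._data = {c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                     for c, (s, e) in sorted(data.items()) if len(s)}
        return obj

    # -- basic protocol -------------------------------------------------------

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, (starts, ends) in self._data.items():
            for s, e in zip(starts, ends):
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][0], other._data[c][0])
            and np.array_equal(self._data[c][1], other._data[c][1])
            for c in self._data
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bases()} bases)"

    @property
    def chroms(self) -> List[str]:
        return list(self._data)

    def spans(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome (empty arrays if absent)."""
        if chrom not in self._data:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._data[chrom]

    def total_bases(self) -> int:
        return int(sum((e - s).sum() for s, e in self._data.values()))

    def is_empty(self) -> bool:
        return not self._data

    # -- membership -----------------------------------------------------------

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 0-based position ``pos`` falls inside the set."""
        starts, ends = self.spans(chrom)
        if not len(starts):
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership for an array of 0-based positions."""
        positions = np.asarray(positions, dtype=np.int64)
        starts, ends = self.spans(chrom)
        if not len(starts):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    # -- set operations -------------------------------------------------------

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Per-base intersection (canonical result)."""
        data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self._data:
            if chrom not in other._data:
                continue
            a_s, a_e = self._data[chrom]
            b_s, b_e = other._data[chrom]
            out_s, out_e = [], []
            i = j = 0
            while i < len(a_s) and j < len(b_s):
                lo = max(a_s[i], b_s[j])
                hi = min(a_e[i], b_e[j])
                if lo < hi:
                    out_s.append(lo)
                    out_e.append(hi)
                if a_e[i] < b_e[j]:
                    i += 1
                else:
                    j += 1
            if out_s:
                data[chrom] = (np.array(out_s), np.array(out_e))
        return IntervalSet._from_arrays(data)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Per-base difference self \\ other."""
        data: Dict[str, Tuple[List[int], List[int]]] = {}
        for chrom, (a_s, a_e) in self._data.items():
            b_s, b_e = other.spans(chrom)
            out_s: List[int] = []
            out_e: List[int] = []
            j = 0
            for s, e in zip(a_s, a_e):
                cur = int(s)
                while j < len(b_s) and b_e[j] <= cur:
                    j += 1
                k = j
                while k < len(b_s) and b_s[k] < e:
                    if b_s[k] > cur:
                        out_s.append(cur)
                        out_e.append(int(b_s[k]))
                    cur = max(cur, int(b_e[k]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out_s.append(cur)
                    out_e.append(int(e))
            if out_s:
                data[chrom] = (np.array(out_s), np.array(out_e))
        return IntervalSet._from_arrays(data)

    def pad(self, flank: int) -> "IntervalSet":
        """Extend every interval by ``flank`` bases on both sides, clip at 0,
        and re-merge.  ``flank`` must be non-negative."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        return IntervalSet(
            GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank)
            for iv in self
        )

    def shrink(self, margin: int) -> "IntervalSet":
        """Trim ``margin`` bases from each end of every interval; intervals
        shorter than ``2*margin`` disappear."""
        if margin < 0:
            raise ValueError("margin must be >= 0")
        ivs = [
            GenomicInterval(iv.chrom, iv.start + margin, iv.end - margin)
            for iv in self
            if len(iv) > 2 * margin
        ]
        return IntervalSet(ivs)


# Alias used throughout spec-facing code paths.
def pad_intervals(s: IntervalSet, flank: int) -> IntervalSet:
    """Pad every interval by ``flank`` bases each side (clip at 0, re-merge)."""
    return s.pad(flank)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-base intersection of two canonical interval sets."""
    return a.intersect(b)


@dataclass
class GeneModel:
    """Mapping gene symbol -> exon intervals."""

    genes: Dict[str, List[GenomicInterval]] = field(default_factory=dict)

    def add_exon(self, gene: str, exon: GenomicInterval) -> None:
        self.genes.setdefault(gene, []).append(exon)

    @classmethod
    def from_bed(cls, path) -> "GeneModel":
        """Read a gene model from a BED file whose name column (4th) holds the
        gene symbol; one line per exon."""
        model = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError("gene-model BED requires a name column")
                model.add_exon(parts[3], GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
        return model


def kit_gene_coverage(genes: GeneModel, kit: IntervalSet) -> Tuple[pd.DataFrame, dict]:
    """Audit a capture/amplification kit design against a gene list.

    For every exon, computes the fraction of its bases addressed by the kit
    target regions; per gene, flags whether any exon is fully missed
    (fraction 0) or only partially addressed (0 < fraction < 1).  The summary
    reports the number of flagged genes and the overall fraction of exon bases
    addressed, aggregated over the union of exon bases (exons of a gene are
    merged per gene before counting so shared bases are not double counted).

    Returns ``(per_exon_table, summary)``.
    """
    rows = []
    total_bases = 0
    covered_bases = 0
    genes_fully_missed = set()
    genes_partial = set()
    for gene in sorted(genes.genes):
        exon_set = IntervalSet(genes.genes[gene])
        total_bases += exon_set.total_bases()
        covered_bases += exon_set.intersect(kit).total_bases()
        for i, exon in enumerate(genes.genes[gene]):
            exon_iv = IntervalSet([exon])
            cov = exon_iv.intersect(kit).total_bases()
            frac = cov / len(exon)
            rows.append(
                {"gene": gene, "exon_index": i, "chrom": exon.chrom,
                 "start": exon.start, "end": exon.end,
                 "covered_fraction": frac}
            )
            if frac == 0.0:
                genes_fully_missed.add(gene)
            elif frac < 1.0:
                genes_partial.add(gene)
    table = pd.DataFrame(rows, columns=["gene", "exon_index", "chrom", "start",
                                        "end", "covered_fraction"])
    summary = {
        "n_genes": len(genes.genes),
        "n_genes_exon_fully_missed": len(genes_fully_missed),
        "n_genes_exon_partial": len(genes_partial),
        "fraction_bases_addressed": (covered_bases / total_bases) if total_bases else float("nan"),
    }
    return table, summary


# -- BED I/O ------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    """Read BED3+ (tab-separated, no header) into a canonical IntervalSet."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return IntervalSet(ivs)


def write_bed(s: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in s:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed_records(path) -> List[Tuple[str, int, int, str]]:
    """Read BED lines preserving order, duplicates and the name column
    (for amplicon/read tables, which may legitimately overlap)."""
    recs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            recs.append((parts[0], int(parts[1]), int(parts[2]), name))
    return recs


def write_bed_records(records: Sequence[Tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
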