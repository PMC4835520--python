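"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately naive (per-base enumeration, exhaustive
search) and independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a VCF-style edit (1-based pos) to a reference string."""
    assert seq[pos - 1:pos - 1 + len(ref)] == ref
    return seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]


def leftmost_indel_position(seq: str, pos: int, ref: str, alt: str,
                            window: int = 60) -> Tuple[int, str, str]:
    """Exhaustively find the left-most minimal anchored representation of a
    pure indel that yields the same haplotype as (pos, ref, alt)."""
    target = apply_edit(seq, pos, ref, alt)
    delta = len(ref) - len(alt)
    assert delta != 0, "oracle is for indels"
    best: Optional[Tuple[int, str, str]] = None
    for p in range(max(1, pos - window), pos + window + 1):
        if delta > 0:   # deletion: ref = anchor + deleted bases, alt = anchor
            if p + delta > len(seq):
                continue
            cand_ref = seq[p - 1:p + delta]
            cand_alt = seq[p - 1]
        else:           # insertion: ref = anchor, alt = anchor + inserted
            cand_ref = seq[p - 1]
            cand_alt = target[p - 1:p - delta]
            if len(cand_alt) != 1 - delta or cand_alt[0] != cand_ref:
                continue
        if len(cand_ref) == 0 or len(cand_alt) == 0:
            continue
        try:
            if apply_edit(seq, p, cand_ref, cand_alt) == target:
                best = (p, cand_ref, cand_alt)
                break   # scanning left to right: first hit is left-most
        except AssertionError:
            continue
    assert best is not None, "oracle failed to find an equivalent representation"
    return best


def denormalized_indel(seq: str, pos: int, ref: str, alt: str,
                       rng: np.random.Generator) -> Tuple[int, str, str]:
    """Produce a messy but equivalent representation of a minimal indel by
    padding with shared flanking reference bases."""
    left = int(rng.integers(0, 4))
    right = int(rng.integers(0, 4))
    new_pos = max(1, pos - left)
    left = pos - new_pos
    lpad = seq[new_pos - 1:pos - 1]
    rstart = pos - 1 + len(ref)
    rpad = seq[rstart:rstart + right]
    return new_pos, lpad + ref + rpad, lpad + alt + rpad


def quantile_oracle(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile recomputed from sorted order."""
    v = sorted(values)
    if len(v) == 1:
        return v[0]
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def depth_sweep_oracle(reads: Sequence[Tuple[str, int, int]],
                       chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base depth by direct counting."""
    out = np.zeros(end - start, dtype=int)
    for c, s, e in reads:
        if c != chrom:
            continue
        for p in range(max(s, start), min(e, end)):
            out[p - start] += 1
    return out


def exhaustive_filter_search(tp: "np.ndarray | dict", fp: dict,
                             grids: Dict[str, Sequence[float]],
                             directions: Dict[str, str],
                             order: Sequence[str],
                             target: float) -> Tuple[int, int]:
    """Independent exhaustive search over a threshold grid.

    ``tp``/``fp`` map parameter name -> value array.  Returns the objective
    of the best feasible combination as (fp_removed, tp_kept), maximizing
    FP removal then TP retention.
    """
    n_tp = len(next(iter(tp.values())))
    n_fp = len(next(iter(fp.values())))
    best = None
    for combo in itertools.product(*(grids[p] for p in order)):
        tp_keep = np.ones(n_tp, dtype=bool)
        fp_keep = np.ones(n_fp, dtype=bool)
        for p, thr in zip(order, combo):
            if directions[p] == "min":
                tp_keep &= tp[p] >= thr
                fp_keep &= fp[p] >= thr
            else:
                tp_keep &= tp[p] <= thr
                fp_keep &= fp[p] <= thr
        kept = int(tp_keep.sum())
        if kept / n_tp < target:
            continue
        obj = (n_fp - int(fp_keep.sum()), kept)
        if best is None or obj > best:
            best = obj
    assert best is not None
    return best
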