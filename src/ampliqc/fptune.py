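"""Caller-parameter profiling and multi-parameter hard-filter tuning.

Five caller parameters discriminate false-positive from true-positive calls:
FAO, FDP, GQ, QUAL and STB for SNPs; FAO, FDP, GQ, QUAL and HRUN for indels.
A filter is a threshold vector over those five parameters; a call is removed
when *any* failing condition holds (GQ < GQ_min, FDP < FDP_min,
QUAL < QUAL_min, FAO < FAO_min, plus STB > STB_max for SNPs or
HRUN > HRUN_max for indels).

:class:`FilterTuner` searches the threshold grid exhaustively for the
combination that removes the most false positives subject to retaining at
least a target fraction of true positives, mirroring ROC-style stringency
presets: low (>=99 % TP retained), medium (>=95 %) and high (>=90 %).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .vcfnorm import NormalizedVariant

__all__ = [
    "PARAMETERS",
    "FILTER_PARAMS",
    "FilterSpec",
    "PRESETS",
    "TuningResult",
    "FilterTuner",
    "tune_thresholds",
    "summarize_parameters",
    "apply_filter",
    "apply_filter_frame",
    "flag_suspect_indels",
]

#: The 11 caller parameters profiled by label.
PARAMETERS = ("AO", "DP", "FAO", "FDP", "FXX", "GQ", "HRUN", "QD", "QUAL",
              "STB", "STBP")

#: The 5 tuning parameters per class, in the fixed tie-break order.
FILTER_PARAMS = {
    "snp": ("GQ", "FDP", "QUAL", "STB", "FAO"),
    "indel": ("GQ", "FDP", "QUAL", "HRUN", "FAO"),
}

#: Direction of each threshold: "min" removes calls below, "max" above.
_DIRECTION = {"GQ": "min", "FDP": "min", "QUAL": "min", "FAO": "min",
              "STB": "max", "HRUN": "max"}

_RETENTION_TO_STRINGENCY = {0.99: "low", 0.95: "medium", 0.90: "high"}


@dataclass(frozen=True)
class FilterSpec:
    """Threshold vector for one variant class at one stringency."""

    variant_class: str            # "snp" | "indel"
    stringency: str               # "low" | "medium" | "high" | "custom"
    gq_min: float
    fdp_min: float
    qual_min: float
    fao_min: float
    stb_max: Optional[float] = None    # SNP only
    hrun_max: Optional[float] = None   # indel only
    target_retention: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant_class not in ("snp", "indel"):
            raise ValueError("variant_class must be 'snp' or 'indel'")
        if self.variant_class == "snp" and self.stb_max is None:
            raise ValueError("SNP filter requires stb_max")
        if self.variant_class == "indel" and self.hrun_max is None:
            raise ValueError("indel filter requires hrun_max")

    def thresholds(self) -> Dict[str, float]:
        """Thresholds keyed by parameter name, in tie-break order."""
        out = {"GQ": self.gq_min, "FDP": self.fdp_min, "QUAL": self.qual_min}
        if self.variant_class == "snp":
            out["STB"] = self.stb_max
        else:
            out["HRUN"] = self.hrun_max
        out["FAO"] = self.fao_min
        return out

    def to_config_lines(self) -> List[str]:
        kv = {"class": self.variant_class, "stringency": self.stringency,
              **{k.lower(): v for k, v in self.thresholds().items()}}
        if self.target_retention is not None:
            kv["target_retention"] = self.target_retention
        return [f"{k}={v}" for k, v in kv.items()]


#: Published preset thresholds for the three stringency levels, shipped as
#: provisional configuration defaults (the tuner re-derives thresholds from
#: training data; these are starting points and grid anchors).
PRESETS: Dict[Tuple[str, str], FilterSpec] = {
    ("indel", "low"): FilterSpec("indel", "low", gq_min=5, fdp_min=10,
                                 qual_min=20, hrun_max=6, fao_min=4,
                                 target_retention=0.99),
    ("indel", "medium"): FilterSpec("indel", "medium", gq_min=8, fdp_min=20,
                                    qual_min=30, hrun_max=5, fao_min=4,
                                    target_retention=0.95),
    ("indel", "high"): FilterSpec("indel", "high", gq_min=10, fdp_min=25,
                                  qual_min=40, hrun_max=4, fao_min=4,
                                  target_retention=0.90),
    ("snp", "low"): FilterSpec("snp", "low", gq_min=5, fdp_min=6,
                               qual_min=20, stb_max=0.90, fao_min=2,
                               target_retention=0.99),
    ("snp", "medium"): FilterSpec("snp", "medium", gq_min=10, fdp_min=6,
                                  qual_min=20, stb_max=0.70, fao_min=2,
                                  target_retention=0.95),
    ("snp", "high"): FilterSpec("snp", "high", gq_min=15, fdp_min=10,
                                qual_min=30, stb_max=0.60, fao_min=2,
                                target_retention=0.90),
}


# -- parameter profiling ------------------------------------------------------

def summarize_parameters(calls: pd.DataFrame, label_col: str = "label",
                         n_bins: int = 20):
    """Quantile summary and histogram of the 11 caller parameters by label.

    ``calls`` is a labelled frame (see :func:`ampliqc.bench.calls_to_frame`).
    A parameter missing on more than half the calls of a label is reported
    as unavailable.  Returns ``(summary_frame, histograms)`` where
    ``histograms[(parameter, label)] = (counts, bin_edges)``.
    """
    rows = []
    histograms: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for label, sub in calls.groupby(label_col):
        for param in PARAMETERS:
            vals = sub[param].to_numpy(dtype=float) if param in sub else np.array([])
            missing = np.isnan(vals).mean() if len(vals) else 1.0
            available = missing <= 0.5 and len(vals) > 0
            row = {"parameter": param, "label": label,
                   "n": int(np.isfinite(vals).sum()),
                   "missing_fraction": float(missing),
                   "available": bool(available)}
            if available:
                v = vals[np.isfinite(vals)]
                qs = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
                row.update(min=qs[0], q25=qs[1], median=qs[2], q75=qs[3],
                           max=qs[4], mean=float(v.mean()))
                counts, edges = np.histogram(v, bins=n_bins)
                histograms[(param, str(label))] = (counts, edges)
            else:
                row.update(min=np.nan, q25=np.nan, median=np.nan,
                           q75=np.nan, max=np.nan, mean=np.nan)
            rows.append(row)
    summary = pd.DataFrame(rows, columns=["parameter", "label", "available",
                                          "n", "missing_fraction", "min",
                                          "q25", "median", "q75", "max",
                                          "mean"])
    return summary, histograms


# -- filter application -------------------------------------------------------

def _fail_mask(values: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    """True where a call fails one threshold; NaN always fails (missing)."""
    with np.errstate(invalid="ignore"):
        if direction == "min":
            fail = values < threshold
        else:
            fail = values > threshold
    return fail | np.isnan(values)


def apply_filter_frame(calls: pd.DataFrame, spec: FilterSpec
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised filter evaluation on a call frame.

    Returns ``(removed, missing)`` boolean masks: ``removed`` marks calls
    failing any threshold, ``missing`` the subset removed only because a
    required parameter is absent.
    """
    n = len(calls)
    removed = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)
    any_real_fail = np.zeros(n, dtype=bool)
    for param, thr in spec.thresholds().items():
        vals = calls[param].to_numpy(dtype=float)
        isnan = np.isnan(vals)
        fail = _fail_mask(vals, thr, _DIRECTION[param])
        removed |= fail
        any_real_fail |= fail & ~isnan
        missing |= isnan
    missing = removed & missing & ~any_real_fail
    return removed, missing


def apply_filter(calls: Sequence[NormalizedVariant], spec: FilterSpec
                 ) -> Tuple[List[NormalizedVariant], List[NormalizedVariant]]:
    """Apply a FilterSpec to normalized calls.

    A call is removed iff any failing condition holds; calls missing a
    required parameter (and failing nothing else) are removed with the
    distinct label ``ts_missing``.  Retained calls get FILTER ``PASS``,
    removed ones ``ts_<stringency>``.  Returns ``(retained, removed)`` with
    the FILTER field set on every record.
    """
    from .bench import calls_to_frame

    frame = calls_to_frame(calls)
    removed_mask, missing_mask = apply_filter_frame(frame, spec)
    retained, removed = [], []
    for v, rm, ms in zip(calls, removed_mask, missing_mask):
        if rm:
            v.filter = "ts_missing" if ms else f"ts_{spec.stringency}"
            removed.append(v)
        else:
            v.filter = "PASS"
            retained.append(v)
    return retained, removed


def flag_suspect_indels(calls: Sequence[NormalizedVariant]) -> pd.DataFrame:
    """Advisory robustness flags for indel calls (never removes anything).

    ``multiallelic_suspect``: the originating VCF record carried >= 3
    alternate alleles; ``long_indel_suspect``: indel length > 100 bp;
    ``homopolymer_context``: caller-reported HRUN >= 5.
    """
    rows = []
    for v in calls:
        hrun = v.annotations.get("HRUN")
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "multiallelic_suspect": v.n_original_alts >= 3,
            "long_indel_suspect": v.indel_length > 100,
            "homopolymer_context": hrun is not None and hrun >= 5,
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "multiallelic_suspect",
                                       "long_indel_suspect",
                                       "homopolymer_context"])


# -- threshold tuning ---------------------------------------------------------

@dataclass
class TuningResult:
    """Outcome of an exhaustive threshold search."""

    spec: FilterSpec
    training_tp_retention: float
    training_fp_removal: float
    n_tp: int
    n_fp: int
    target_retention: float
    grid_sizes: Dict[str, int]
    n_combinations: int
    n_feasible: int
    n_ties: int
    candidate_grids: Dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Filter tuning ({self.spec.variant_class}, "
            f"{self.spec.stringency} stringency)",
            "=" * 46,
            f"training calls:      {self.n_tp} TP / {self.n_fp} FP",
            f"target TP retention: {self.target_retention:.0%}",
            f"achieved retention:  {self.training_tp_retention:.2%}",
            f"FP removal:          {self.training_fp_removal:.2%}",
            f"grid: " + ", ".join(f"{k}={v}" for k, v in self.grid_sizes.items())
            + f" ({self.n_combinations} combinations, "
              f"{self.n_feasible} feasible, {self.n_ties} ties)",
            "selected thresholds:",
        ]
        for param, thr in self.spec.thresholds().items():
            op = "<" if _DIRECTION[param] == "min" else ">"
            lines.append(f"  remove if {param} {op} {thr:g}")
        return "\n".join(lines)


class FilterTuner:
    """Exhaustive grid search for class-specific filter thresholds.

    Built from a labelled training frame (columns: the caller parameters plus
    ``label`` in {"tp", "fp"} and ``variant_class``); :meth:`fit` returns a
    :class:`TuningResult` whose spec retains at least ``target_retention`` of
    training true positives while maximizing false-positive removal.

    Candidate thresholds per parameter are the deciles of the TP distribution
    plus the published preset threshold for the targeted stringency, so the
    search space stays below 12^5 combinations.  Ties are broken toward
    higher TP retention, then toward more permissive thresholds in the fixed
    order GQ, FDP, QUAL, HRUN/STB, FAO.
    """

    def __init__(self, calls: pd.DataFrame, variant_class: str,
                 target_retention: float,
                 n_quantiles: int = 11,
                 include_presets: bool = True,
                 per_sample: bool = False):
        if variant_class not in FILTER_PARAMS:
            raise ValueError("variant_class must be 'snp' or 'indel'")
        if not 0 < target_retention <= 1:
            raise ValueError("target_retention must be in (0, 1]")
        sub = calls
        if "variant_class" in calls.columns:
            sub = calls[calls["variant_class"] == variant_class]
        labels = sub["label"].str.lower()
        self.tp = sub[labels == "tp"]
        self.fp = sub[labels == "fp"]
        if not len(self.tp) or not len(self.fp):
            raise ValueError("training data must contain both TP and FP calls")
        self.variant_class = variant_class
        self.target_retention = float(target_retention)
        self.n_quantiles = int(n_quantiles)
        self.include_presets = include_presets
        self.per_sample = per_sample
        if per_sample and "sample" not in sub.columns:
            raise ValueError("per-sample retention requires a 'sample' column")

    @classmethod
    def from_dataframe(cls, calls: pd.DataFrame, variant_class: str,
                       target_retention: float, **kw) -> "FilterTuner":
        return cls(calls, variant_class, target_retention, **kw)

    # -- grid construction ----------------------------------------------------

    def _candidate_grid(self) -> Dict[str, np.ndarray]:
        params = FILTER_PARAMS[self.variant_class]
        stringency = _RETENTION_TO_STRINGENCY.get(round(self.target_retention, 2))
        preset = (PRESETS.get((self.variant_class, stringency))
                  if (self.include_presets and stringency) else None)
        grids = {}
        qs = np.linspace(0.0, 1.0, self.n_quantiles)
        for param in params:
            vals = self.tp[param].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            cands = np.quantile(vals, qs)
            if preset is not None:
                cands = np.append(cands, preset.thresholds()[param])
            grids[param] = np.unique(cands)
        return grids

    # -- search ---------------------------------------------------------------

    def fit(self) -> TuningResult:
        params = FILTER_PARAMS[self.variant_class]
        grids = self._candidate_grid()
        tp_pass = []
        fp_pass = []
        perm_rank = []   # per param: rank arrays, 0 = most permissive
        for param in params:
            cands = grids[param]
            tvals = self.tp[param].to_numpy(dtype=float)
            fvals = self.fp[param].to_numpy(dtype=float)
            tp_pass.append(np.stack([~_fail_mask(tvals, c, _DIRECTION[param])
                                     for c in cands]))
            fp_pass.append(np.stack([~_fail_mask(fvals, c, _DIRECTION[param])
                                     for c in cands]))
            n = len(cands)
            if _DIRECTION[param] == "min":
                perm_rank.append(np.arange(n))          # lower threshold = permissive
            else:
                perm_rank.append(np.arange(n)[::-1])    # higher threshold = permissive

        n_tp, n_fp = len(self.tp), len(self.fp)
        if self.per_sample:
            samp_codes = pd.Categorical(self.tp["sample"]).codes
            samp_totals = np.bincount(samp_codes)

        best_key = None
        best_combo = None
        n_feasible = 0
        n_ties = 0
        sizes = [len(grids[p]) for p in params]
        n_comb = int(np.prod(sizes))

        # depth-first over the grid with prefix ANDs so each level's mask is
        # computed once per branch
        idx = [0] * 5
        tp_prefix = [None] * 5
        fp_prefix = [None] * 5

        def prefix(level: int) -> None:
            t = tp_pass[level][idx[level]]
            f = fp_pass[level][idx[level]]
            if level:
                t = t & tp_prefix[level - 1]
                f = f & fp_prefix[level - 1]
            tp_prefix[level] = t
            fp_prefix[level] = f

        for idx[0] in range(sizes[0]):
            prefix(0)
            for idx[1] in range(sizes[1]):
                prefix(1)
                for idx[2] in range(sizes[2]):
                    prefix(2)
                    for idx[3] in range(sizes[3]):
                        prefix(3)
                        for idx[4] in range(sizes[4]):
                            tp_keep = tp_pass[4][idx[4]] & tp_prefix[3]
                            tp_kept = int(np.count_nonzero(tp_keep))
                            if tp_kept / n_tp < self.target_retention:
                                continue
                            if self.per_sample:
                                kept_per = np.bincount(
                                    samp_codes[tp_keep],
                                    minlength=len(samp_totals))
                                if np.any(kept_per / samp_totals
                                          < self.target_retention):
                                    continue
                            n_feasible += 1
                            fp_keep = fp_pass[4][idx[4]] & fp_prefix[3]
                            fp_removed = n_fp - int(np.count_nonzero(fp_keep))
                            key = (fp_removed, tp_kept,
                                   -int(perm_rank[0][idx[0]]),
                                   -int(perm_rank[1][idx[1]]),
                                   -int(perm_rank[2][idx[2]]),
                                   -int(perm_rank[3][idx[3]]),
                                   -int(perm_rank[4][idx[4]]))
                            if best_key is None or key > best_key:
                                best_key = key
                                best_combo = tuple(idx)
                                n_ties = 0
                            elif key[:2] == best_key[:2]:
                                n_ties += 1

        assert best_key is not None, (
            "no feasible combination: the all-permissive grid point should "
            "always satisfy retention")

        thr = {p: float(grids[p][i]) for p, i in zip(params, best_combo)}
        stringency = _RETENTION_TO_STRINGENCY.get(
            round(self.target_retention, 2), "custom")
        kw = dict(variant_class=self.variant_class, stringency=stringency,
                  gq_min=thr["GQ"], fdp_min=thr["FDP"], qual_min=thr["QUAL"],
                  fao_min=thr["FAO"], target_retention=self.target_retention)
        if self.variant_class == "snp":
            kw["stb_max"] = thr["STB"]
        else:
            kw["hrun_max"] = thr["HRUN"]
        spec = FilterSpec(**kw)

        retention = best_key[1] / n_tp
        assert retention >= self.target_retention
        return TuningResult(
            spec=spec,
            training_tp_retention=retention,
            training_fp_removal=best_key[0] / n_fp,
            n_tp=n_tp, n_fp=n_fp,
            target_retention=self.target_retention,
            grid_sizes={p: len(grids[p]) for p in params},
            n_combinations=n_comb,
            n_feasible=n_feasible,
            n_ties=n_ties,
            candidate_grids=grids,
        )


def tune_thresholds(calls: pd.DataFrame, variant_class: str,
                    target_retention: float, **kw) -> TuningResult:
    """Convenience wrapper around :class:`FilterTuner`."""
    return FilterTuner(calls, variant_class, target_retention, **kw).fit()
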