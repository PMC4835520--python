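"""Coverage metrics, GC-stratified amplicon statistics, hard-to-sequence
region classification, random read downsampling and coverage/variant-loss
curve fits.

Depth is modelled per base over target regions (bedGraph semantics).  The
headline metrics follow amplicon-exome practice: mean coverage, breadth at
20x (fraction of target bases with depth >= 20), uniformity (fraction of
target bases with depth >= 20 % of the mean) and the inter-quartile range of
base depth.  Downsampling keeps each read independently with probability
target_mean / current_mean, emulating random read thinning; a variant is
considered lost after thinning when its site depth falls below 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .regions import GenomicInterval, IntervalSet

__all__ = [
    "DepthTrack",
    "CoverageSummary",
    "AmpliconStat",
    "region_depth_summary",
    "amplicon_stats",
    "amplicon_cohort_summary",
    "exon_coverage_table",
    "hard_region_classifier",
    "downsample_reads",
    "build_downsample_series",
    "CoverageCurveModel",
    "CoverageCurveResult",
    "fit_coverage_curves",
]

#: Depth threshold below which a site is not callable after downsampling.
CALLABILITY_DEPTH = 20

#: GC-content class boundaries (fractions).
GC_HIGH = 0.75
GC_LOW = 0.25


class DepthTrack:
    """Per-base read depth over genomic spans (bedGraph semantics).

    Spans are non-overlapping, sorted, 0-based half-open; bases outside every
    span carry *no data* (``value_at`` returns ``None``), which summaries may
    choose to treat as depth 0.
    """

    def __init__(self, spans: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # spans: chrom -> (starts, ends, depths)
        self._spans: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sorted(spans):
            s, e, d = spans[chrom]
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            d = np.asarray(d, dtype=np.float64)
            order = np.argsort(s)
            s, e, d = s[order], e[order], d[order]
            if np.any(d < 0):
                raise ValueError("negative depth")
            if np.any(s[1:] < e[:-1]):
                raise ValueError("overlapping depth spans")
            self._spans[chrom] = (s, e, d)

    @classmethod
    def from_reads(cls, reads: pd.DataFrame, targets: IntervalSet) -> "DepthTrack":
        """Pile up reads (columns chrom/start/end) over ``targets``.

        Every target base gets an explicit value (0 where no read covers it),
        so downstream consumers can distinguish "no data" from "zero depth".
        """
        spans = {}
        for chrom in targets.chroms:
            t_s, t_e = targets.spans(chrom)
            lo, hi = int(t_s[0]), int(t_e[-1])
            diff = np.zeros(hi - lo + 1, dtype=np.int64)
            sub = reads[reads["chrom"] == chrom]
            if len(sub):
                starts = np.clip(sub["start"].to_numpy() - lo, 0, hi - lo)
                ends = np.clip(sub["end"].to_numpy() - lo, 0, hi - lo)
                np.add.at(diff, starts, 1)
                np.add.at(diff, ends, -1)
            depth = np.cumsum(diff[:-1])
            out_s, out_e, out_d = [], [], []
            for s, e in zip(t_s, t_e):
                seg = depth[s - lo:e - lo]
                # run-length encode
                change = np.flatnonzero(np.diff(seg)) + 1
                bounds = np.concatenate([[0], change, [len(seg)]])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    out_s.append(int(s + a))
                    out_e.append(int(s + b))
                    out_d.append(float(seg[a]))
            spans[chrom] = (np.array(out_s), np.array(out_e), np.array(out_d))
        return cls(spans)

    @classmethod
    def from_bedgraph(cls, path) -> "DepthTrack":
        per: Dict[str, List[Tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, s, e, d = line.split("\t")
                per.setdefault(chrom, []).append((int(s), int(e), float(d)))
        spans = {}
        for chrom, rows in per.items():
            rows.sort()
            spans[chrom] = (np.array([r[0] for r in rows]),
                            np.array([r[1] for r in rows]),
                            np.array([r[2] for r in rows]))
        return cls(spans)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (s, e, d) in self._spans.items():
                for a, b, v in zip(s, e, d):
                    v_str = f"{v:g}"
                    fh.write(f"{chrom}\t{a}\t{b}\t{v_str}\n")

    @property
    def chroms(self) -> List[str]:
        return list(self._spans)

    def value_at(self, chrom: str, pos0: int) -> Optional[float]:
        """Depth at a 0-based position; None where the track has no data."""
        if chrom not in self._spans:
            return None
        s, e, d = self._spans[chrom]
        i = int(np.searchsorted(s, pos0, side="right")) - 1
        if i >= 0 and pos0 < e[i]:
            return float(d[i])
        return None

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised depth lookup; NaN where the track has no data."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), np.nan)
        if chrom not in self._spans:
            return out
        s, e, d = self._spans[chrom]
        idx = np.searchsorted(s, positions, side="right") - 1
        ok = (idx >= 0) & (positions < e[np.clip(idx, 0, None)])
        out[ok] = d[idx[ok]]
        return out

    def per_base(self, regions: IntervalSet) -> np.ndarray:
        """Depth of every base of ``regions``, missing data as 0."""
        chunks = []
        for chrom in regions.chroms:
            r_s, r_e = regions.spans(chrom)
            for a, b in zip(r_s, r_e):
                vals = self.values_at(chrom, np.arange(a, b))
                chunks.append(np.nan_to_num(vals, nan=0.0))
        if not chunks:
            return np.empty(0)
        return np.concatenate(chunks)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean depth over [start, end), missing data as 0."""
        vals = self.values_at(chrom, np.arange(start, end))
        return float(np.nan_to_num(vals, nan=0.0).mean())


@dataclass
class CoverageSummary:
    mean_coverage: float
    breadth_k: float
    k: int
    uniformity: float
    iqr: float
    n_bases: int
    quantile_method: str = "median_unbiased"


def region_depth_summary(track: DepthTrack, targets: IntervalSet,
                         k: int = 20) -> CoverageSummary:
    """Depth/breadth summary over target regions.

    Bases with no track data count as depth 0.  IQR uses the median-unbiased
    quantile convention (recorded in the output).
    """
    if targets.is_empty():
        raise ValueError("empty target set")
    depths = track.per_base(targets)
    mean = float(depths.mean())
    q1, q3 = np.quantile(depths, [0.25, 0.75], method="median_unbiased")
    return CoverageSummary(
        mean_coverage=mean,
        breadth_k=float((depths >= k).mean()),
        k=k,
        uniformity=float((depths >= 0.2 * mean).mean()),
        iqr=float(q3 - q1),
        n_bases=len(depths),
    )


@dataclass
class AmpliconStat:
    name: str
    chrom: str
    start: int
    end: int
    n_reads: int
    reads_per_million: float
    mean_depth: float
    gc: float
    gc_class: str


def _gc_class(gc: float) -> str:
    if gc > GC_HIGH:
        return "high"
    if gc < GC_LOW:
        return "low"
    return "mid"


def _assign_reads(reads: pd.DataFrame,
                  amplicons: Sequence[Tuple[str, int, int, str]]) -> np.ndarray:
    """Assign each read to the amplicon with maximal overlap; ties go to the
    left-most amplicon.  Returns per-read amplicon index (-1 = unassigned)."""
    by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    for i, (chrom, s, e, _name) in enumerate(amplicons):
        by_chrom.setdefault(chrom, []).append((s, e, i))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    assign = np.full(len(reads), -1, dtype=np.int64)
    max_len = max((e - s for _c, s, e, _n in amplicons), default=0)
    for row_i, (chrom, rs, re_) in enumerate(
            zip(reads["chrom"].to_numpy(), reads["start"].to_numpy(),
                reads["end"].to_numpy())):
        amps = by_chrom.get(chrom)
        if not amps:
            continue
        starts = [a[0] for a in amps]
        lo = np.searchsorted(starts, rs - max_len)
        best_ov, best_key = 0, None
        for s, e, idx in amps[lo:]:
            if s >= re_:
                break
            ov = min(e, re_) - max(s, rs)
            if ov > best_ov or (ov == best_ov and ov > 0 and best_key is not None
                                and s < best_key[0]):
                best_ov, best_key = ov, (s, idx)
        if best_key is not None:
            assign[row_i] = best_key[1]
    return assign


def amplicon_stats(reads: pd.DataFrame,
                   amplicons: Sequence[Tuple[str, int, int, str]],
                   reference: Mapping[str, str]) -> List[AmpliconStat]:
    """Per-amplicon coverage and GC statistics for one sample.

    ``reads`` has columns chrom/start/end; assignment is by maximal overlap
    (ties to the left-most amplicon).  Mean depth is the per-base mean within
    the amplicon computed from all reads overlapping it.
    """
    for chrom, s, e, name in amplicons:
        if e <= s:
            raise ValueError(f"zero-length amplicon {name}")
    assign = _assign_reads(reads, amplicons)
    n_total = len(reads)
    counts = np.bincount(assign[assign >= 0], minlength=len(amplicons))
    track_targets = IntervalSet(
        GenomicInterval(c, s, e) for c, s, e, _ in amplicons)
    track = DepthTrack.from_reads(reads, track_targets)
    out = []
    for i, (chrom, s, e, name) in enumerate(amplicons):
        seq = str(reference[chrom][s:e]).upper()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        out.append(AmpliconStat(
            name=name, chrom=chrom, start=s, end=e,
            n_reads=int(counts[i]),
            reads_per_million=float(counts[i] / (n_total / 1e6)) if n_total else 0.0,
            mean_depth=track.mean_over(chrom, s, e),
            gc=gc, gc_class=_gc_class(gc),
        ))
    return out


def amplicon_cohort_summary(per_sample: Mapping[str, Sequence[AmpliconStat]],
                            low_depth: float = 10.0) -> pd.DataFrame:
    """Cohort view: per-amplicon mean depth across samples, GC class and a
    flag for amplicons whose cross-sample mean depth is below ``low_depth``."""
    frames = []
    for sid, stats_ in per_sample.items():
        frames.append(pd.DataFrame([{
            "sample": sid, "name": a.name, "gc": a.gc, "gc_class": a.gc_class,
            "mean_depth": a.mean_depth, "reads_per_million": a.reads_per_million,
        } for a in stats_]))
    df = pd.concat(frames, ignore_index=True)
    agg = df.groupby(["name", "gc_class"], as_index=False).agg(
        gc=("gc", "first"), mean_depth=("mean_depth", "mean"),
        reads_per_million=("reads_per_million", "mean"))
    agg["low_coverage"] = agg["mean_depth"] < low_depth
    return agg


def exon_coverage_table(track: DepthTrack,
                        exons: Sequence[Tuple[str, int, int, str]],
                        sample: str) -> pd.DataFrame:
    """Per-exon mean depth and covered fraction (bases with depth >= 1)."""
    rows = []
    for chrom, s, e, name in exons:
        vals = np.nan_to_num(track.values_at(chrom, np.arange(s, e)), nan=0.0)
        rows.append({"sample": sample, "exon": name, "chrom": chrom,
                     "start": s, "end": e,
                     "mean_depth": float(vals.mean()),
                     "covered_fraction": float((vals >= 1).mean())})
    return pd.DataFrame(rows)


def hard_region_classifier(table: pd.DataFrame,
                           low_depth: float = 10.0,
                           partial_fractions: Sequence[float] = (0.5, 0.25, 0.1),
                           ) -> pd.DataFrame:
    """Classify exons that fail coverage thresholds in *every* sample.

    ``table`` holds per-sample exon coverage rows (columns sample, exon,
    mean_depth, covered_fraction).  An exon missing from a sample's rows is
    treated as depth 0 / fraction 0 for that sample (noted in the output).
    Flags: ``always_low`` (mean depth < ``low_depth`` in all samples) and
    ``partial_f`` for each f (covered fraction < f in all samples); the
    partial classes are nested by construction.
    """
    samples = sorted(table["sample"].unique())
    if len(samples) < 2:
        raise ValueError("hard-region classification requires >= 2 samples")
    depth = table.pivot_table(index="exon", columns="sample",
                              values="mean_depth", aggfunc="first")
    frac = table.pivot_table(index="exon", columns="sample",
                             values="covered_fraction", aggfunc="first")
    missing = depth.isna().any(axis=1)
    depth = depth.fillna(0.0)
    frac = frac.fillna(0.0)
    out = pd.DataFrame(index=depth.index)
    out["always_low"] = (depth < low_depth).all(axis=1)
    for f in sorted(partial_fractions, reverse=True):
        out[f"partial_{f}"] = (frac < f).all(axis=1)
    out["had_missing_sample"] = missing
    return out.reset_index()


def downsample_reads(reads: pd.DataFrame, targets: IntervalSet,
                     target_mean: float, seed: int
                     ) -> Tuple[pd.DataFrame, DepthTrack]:
    """Randomly thin reads to a target mean coverage.

    Each read is kept independently with probability
    ``target_mean / current_mean``; the depth track is recomputed from the
    retained reads.  Rejects targets above the current mean.
    """
    current = DepthTrack.from_reads(reads, targets).per_base(targets).mean()
    if target_mean > current:
        raise ValueError(f"target mean {target_mean} exceeds current {current:.1f}")
    p = float(target_mean / current)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < p
    kept = reads.loc[keep].reset_index(drop=True)
    return kept, DepthTrack.from_reads(kept, targets)


def build_downsample_series(reads: pd.DataFrame, targets: IntervalSet,
                            variant_sites: Sequence[Tuple[str, int]],
                            levels: Sequence[float], seed: int,
                            callability_depth: int = CALLABILITY_DEPTH
                            ) -> pd.DataFrame:
    """Thin a read set to each target mean in ``levels`` and record breadth
    and the fraction of variant sites rendered uncallable (site depth below
    ``callability_depth``).  ``variant_sites`` holds (chrom, 0-based pos)."""
    rows = []
    rng = np.random.default_rng(seed)
    for level in sorted(levels, reverse=True):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        kept, track = downsample_reads(reads, targets, level, sub_seed)
        summary = region_depth_summary(track, targets, k=callability_depth)
        by_chrom: Dict[str, List[int]] = {}
        for chrom, pos in variant_sites:
            by_chrom.setdefault(chrom, []).append(pos)
        n_lost = 0
        for chrom, positions in by_chrom.items():
            d = np.nan_to_num(track.values_at(chrom, np.array(positions)), nan=0.0)
            n_lost += int((d < callability_depth).sum())
        rows.append({
            "target_mean": level,
            "realized_mean": summary.mean_coverage,
            "breadth_20": summary.breadth_k,
            "variant_loss": n_lost / len(variant_sites) if variant_sites else np.nan,
            "n_reads": len(kept),
        })
    return pd.DataFrame(rows).sort_values("target_mean").reset_index(drop=True)


# -- curve fits ---------------------------------------------------------------

def _breadth_model(mean: np.ndarray, m0: float, tau: float) -> np.ndarray:
    return np.clip(1.0 - np.exp(-(mean - m0) / tau), 0.0, 1.0)


@dataclass
class CoverageCurveResult:
    """Fitted coverage/variant-loss relationships for a downsampling series.

    ``breadth_20(mean) = 1 - exp(-(mean - m0)/tau)`` (clipped to [0, 1]) and
    ``variant_loss(breadth) = a + b * breadth``, each with its r^2.
    """

    m0: float
    tau: float
    exp_r2: float
    loss_intercept: float
    loss_slope: float
    linear_r2: float
    n_levels: int
    series: pd.DataFrame

    def predict_breadth(self, mean) -> np.ndarray:
        return _breadth_model(np.asarray(mean, dtype=float), self.m0, self.tau)

    def predict_loss(self, breadth) -> np.ndarray:
        return self.loss_intercept + self.loss_slope * np.asarray(breadth, dtype=float)

    def summary(self) -> str:
        lines = [
            "Coverage curve fits",
            "===================",
            f"levels fitted:        {self.n_levels}",
            f"breadth_20(mean) = 1 - exp(-(mean - m0)/tau)",
            f"  m0  = {self.m0:10.3f}",
            f"  tau = {self.tau:10.3f}",
            f"  r^2 = {self.exp_r2:10.4f}",
            f"loss(breadth) = a + b * breadth",
            f"  a   = {self.loss_intercept:10.4f}",
            f"  b   = {self.loss_slope:10.4f}",
            f"  r^2 = {self.linear_r2:10.4f}",
        ]
        return "\n".join(lines)


class CoverageCurveModel:
    """Least-squares model for the two downsampling relationships.

    Built from a series table (columns ``realized_mean``, ``breadth_20``,
    ``variant_loss``); :meth:`fit` returns a :class:`CoverageCurveResult`.
    """

    def __init__(self, series: pd.DataFrame):
        required = {"realized_mean", "breadth_20", "variant_loss"}
        if not required <= set(series.columns):
            raise ValueError(f"series must carry columns {sorted(required)}")
        if len(series) < 4:
            raise ValueError("need >= 4 downsampling levels to fit")
        self.series = series.sort_values("realized_mean").reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, series: pd.DataFrame) -> "CoverageCurveModel":
        return cls(series)

    def fit(self) -> CoverageCurveResult:
        mean = self.series["realized_mean"].to_numpy(dtype=float)
        breadth = self.series["breadth_20"].to_numpy(dtype=float)
        loss = self.series["variant_loss"].to_numpy(dtype=float)

        if np.allclose(breadth, breadth[0]):
            m0, tau, exp_r2 = np.nan, np.nan, np.nan
        else:
            tau0 = max((mean.max() - mean.min()) / 2.0, 1.0)
            (m0, tau), _ = optimize.curve_fit(
                lambda m, m0_, tau_: 1.0 - np.exp(-(m - m0_) / tau_),
                mean, breadth, p0=[mean.min() / 2.0, tau0], maxfev=20000)
            pred = _breadth_model(mean, m0, tau)
            ss_res = float(((breadth - pred) ** 2).sum())
            ss_tot = float(((breadth - breadth.mean()) ** 2).sum())
            exp_r2 = 1.0 - ss_res / ss_tot

        if np.allclose(loss, loss[0]) or np.allclose(breadth, breadth[0]):
            a, b, lin_r2 = np.nan, np.nan, np.nan
        else:
            res = stats.linregress(breadth, loss)
            a, b, lin_r2 = float(res.intercept), float(res.slope), float(res.rvalue ** 2)

        return CoverageCurveResult(
            m0=float(m0), tau=float(tau), exp_r2=float(exp_r2),
            loss_intercept=a, loss_slope=b, linear_r2=lin_r2,
            n_levels=len(self.series), series=self.series,
        )


def fit_coverage_curves(series: pd.DataFrame) -> CoverageCurveResult:
    """Convenience wrapper: fit both downsampling relationships."""
    return CoverageCurveModel(series).fit()
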