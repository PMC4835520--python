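"""Depth summaries, amplicon/GC statistics, hard regions, downsampling and
curve fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ampliqc.covstats import (CoverageCurveModel, DepthTrack,
                              amplicon_stats, build_downsample_series,
                              downsample_reads, exon_coverage_table,
                              fit_coverage_curves, hard_region_classifier,
                              region_depth_summary)
from ampliqc.regions import IntervalSet

from _oracles import depth_sweep_oracle, quantile_oracle


def track_from_array(depths, start=0, chrom="chr1"):
    pos = np.arange(start, start + len(depths))
    return DepthTrack({chrom: (pos, pos + 1, np.asarray(depths, dtype=float))})


class TestDepthTrack:
    def test_reads_pileup_matches_sweep_oracle(self, rng):
        targets = IntervalSet.from_spans("chr1", [(0, 300)])
        reads = pd.DataFrame({
            "chrom": "chr1",
            "start": rng.integers(0, 250, size=100),
        })
        reads["end"] = reads["start"] + rng.integers(10, 50, size=100)
        track = DepthTrack.from_reads(reads, targets)
        oracle = depth_sweep_oracle(
            list(reads[["chrom", "start", "end"]].itertuples(index=False,
                                                             name=None)),
            "chr1", 0, 300)
        got = np.nan_to_num(track.values_at("chr1", np.arange(300)), nan=0.0)
        assert np.array_equal(got, oracle)

    def test_bedgraph_round_trip(self, tmp_path, rng):
        track = track_from_array(rng.integers(0, 50, size=40), start=10)
        path = tmp_path / "d.bedgraph"
        track.to_bedgraph(path)
        back = DepthTrack.from_bedgraph(path)
        pts = np.arange(5, 60)
        a = track.values_at("chr1", pts)
        b = back.values_at("chr1", pts)
        assert np.array_equal(np.isnan(a), np.isnan(b))
        assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)])


class TestRegionDepthSummary:
    def test_constant_depth(self):
        track = track_from_array([30] * 100)
        s = region_depth_summary(track, IntervalSet.from_spans("chr1", [(0, 100)]))
        assert s.uniformity == 1.0
        assert s.breadth_k == 1.0
        assert s.iqr == 0.0

    def test_two_level_uniformity(self):
        # depths [100, 10]: mean 55, threshold 11, only the 100-depth half passes
        track = track_from_array([100] * 50 + [10] * 50)
        s = region_depth_summary(track, IntervalSet.from_spans("chr1", [(0, 100)]))
        assert s.mean_coverage == pytest.approx(55.0)
        assert s.uniformity == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        depths = rng.integers(0, 120, size=400).astype(float)
        track = track_from_array(depths)
        targets = IntervalSet.from_spans("chr1", [(50, 200), (250, 380)])
        s = region_depth_summary(track, targets, k=20)
        sel = np.concatenate([depths[50:200], depths[250:380]])
        assert s.mean_coverage == pytest.approx(sel.mean(), abs=1e-9)
        assert s.breadth_k == pytest.approx((sel >= 20).mean(), abs=1e-9)
        assert s.uniformity == pytest.approx(
            (sel >= 0.2 * sel.mean()).mean(), abs=1e-9)

    def test_breadth_monotone_in_k(self, rng):
        track = track_from_array(rng.integers(0, 100, size=300))
        targets = IntervalSet.from_spans("chr1", [(0, 300)])
        breadths = [region_depth_summary(track, targets, k=k).breadth_k
                    for k in (1, 10, 20, 40, 80)]
        assert all(a >= b for a, b in zip(breadths, breadths[1:]))

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            region_depth_summary(track_from_array([1]), IntervalSet())


class TestAmpliconStats:
    def test_gc_classes_and_rpm(self):
        ref = {"chr1": "G" * 100 + "A" * 100 + "GCGCAT" * 20}
        amplicons = [("chr1", 0, 100, "ampG"), ("chr1", 100, 200, "ampA"),
                     ("chr1", 200, 320, "ampMix")]
        reads = pd.DataFrame({
            "chrom": ["chr1"] * 6,
            "start": [0, 0, 100, 200, 200, 200],
            "end": [100, 100, 200, 320, 320, 320],
        })
        out = {a.name: a for a in amplicon_stats(reads, amplicons, ref)}
        assert out["ampG"].gc == 1.0 and out["ampG"].gc_class == "high"
        assert out["ampA"].gc == 0.0 and out["ampA"].gc_class == "low"
        assert out["ampMix"].gc_class == "mid"
        # 2 of 6 reads -> 2/6e-6 per million
        assert out["ampG"].reads_per_million == pytest.approx(2 / (6 / 1e6))
        assert out["ampG"].mean_depth == pytest.approx(2.0)

    def test_reads_per_million_arithmetic(self):
        # 300 of 1.5 M reads = 200 reads per million
        assert 300 / (1_500_000 / 1e6) == pytest.approx(200.0)
        ref = {"chr1": "ACGT" * 50}
        amplicons = [("chr1", 0, 100, "a0")]
        reads = pd.DataFrame({"chrom": ["chr1"] * 10, "start": [0] * 10,
                              "end": [100] * 10})
        (a0,) = amplicon_stats(reads, amplicons, ref)
        assert a0.reads_per_million == pytest.approx(10 / (10 / 1e6))

    def test_maximal_overlap_assignment_ties_left(self):
        ref = {"chr1": "A" * 400}
        amplicons = [("chr1", 0, 100, "left"), ("chr1", 100, 200, "right")]
        # read overlapping both equally -> assigned to left-most
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150]})
        out = {a.name: a for a in amplicon_stats(reads, amplicons, ref)}
        assert out["left"].n_reads == 1
        assert out["right"].n_reads == 0

    def test_zero_length_amplicon_rejected(self):
        with pytest.raises(ValueError):
            amplicon_stats(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                           [("chr1", 5, 5, "bad")], {"chr1": "A" * 10})


class TestHardRegions:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "exon", "mean_depth",
                                           "covered_fraction"])

    def test_always_low(self):
        t = self.table([("s1", "e1", 8, 1.0), ("s2", "e1", 9, 1.0),
                        ("s3", "e1", 7, 1.0)])
        out = hard_region_classifier(t).set_index("exon")
        assert bool(out.loc["e1", "always_low"])

    def test_fully_covered_no_flags(self):
        t = self.table([("s1", "e1", 80, 1.0), ("s2", "e1", 90, 1.0)])
        out = hard_region_classifier(t).set_index("exon")
        row = out.loc["e1"]
        assert not row[["always_low", "partial_0.5", "partial_0.25",
                        "partial_0.1"]].any()

    def test_partial_thresholds_nested(self):
        t = self.table([("s1", "e1", 30, 0.40), ("s2", "e1", 30, 0.45),
                        ("s3", "e1", 30, 0.30)])
        out = hard_region_classifier(t).set_index("exon")
        row = out.loc["e1"]
        assert bool(row["partial_0.5"])
        assert not row["partial_0.25"] and not row["partial_0.1"]

    def test_missing_sample_treated_as_zero(self):
        t = self.table([("s1", "e1", 50, 1.0), ("s2", "e1", 50, 1.0),
                        ("s1", "e2", 50, 1.0)])   # e2 absent from s2
        out = hard_region_classifier(t).set_index("exon")
        assert bool(out.loc["e2", "had_missing_sample"])
        assert not out.loc["e2", "always_low"]     # s1 has depth 50


class TestDownsampling:
    def make_reads(self, rng, n=10_000, span=5_000):
        starts = rng.integers(0, span - 60, size=n)
        return pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": starts + 50,
                             "name": [f"r{i}" for i in range(n)]})

    def test_identity_at_current_mean(self, rng):
        reads = self.make_reads(rng, n=2000)
        targets = IntervalSet.from_spans("chr1", [(0, 5000)])
        current = DepthTrack.from_reads(reads, targets).per_base(targets).mean()
        kept, _ = downsample_reads(reads, targets, current, seed=3)
        assert len(kept) == len(reads)

    def test_target_above_current_rejected(self, rng):
        reads = self.make_reads(rng, n=500)
        targets = IntervalSet.from_spans("chr1", [(0, 5000)])
        with pytest.raises(ValueError):
            downsample_reads(reads, targets, 10_000.0, seed=1)

    def test_retained_count_in_binomial_band(self, rng):
        reads = self.make_reads(rng, n=10_000)
        targets = IntervalSet.from_spans("chr1", [(0, 5000)])
        current = DepthTrack.from_reads(reads, targets).per_base(targets).mean()
        kept, _ = downsample_reads(reads, targets, current / 2, seed=77)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= len(kept) <= hi

    def test_realized_mean_tracks_thinning_probability(self, rng):
        reads = self.make_reads(rng, n=4000)
        targets = IntervalSet.from_spans("chr1", [(0, 5000)])
        current = DepthTrack.from_reads(reads, targets).per_base(targets).mean()
        means = []
        for rep in range(25):
            _, track = downsample_reads(reads, targets, current * 0.4,
                                        seed=1000 + rep)
            means.append(track.per_base(targets).mean())
        assert np.mean(means) == pytest.approx(current * 0.4, rel=0.03)


class TestCurveFits:
    def test_exact_linear_loss_r2_one(self):
        breadth = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        series = pd.DataFrame({
            "realized_mean": [20, 30, 40, 60, 90],
            "breadth_20": breadth,
            "variant_loss": 0.5 - 0.45 * breadth,
        })
        res = fit_coverage_curves(series)
        assert res.linear_r2 == pytest.approx(1.0)
        assert res.loss_slope == pytest.approx(-0.45)

    def test_breadth_parameter_recovery(self, rng):
        m0, tau = 10.0, 40.0
        mean = np.array([20, 30, 40, 50, 60, 70, 80, 90], dtype=float)
        breadth = 1 - np.exp(-(mean - m0) / tau)
        breadth = np.clip(breadth + rng.normal(0, 0.004, size=len(mean)), 0, 1)
        series = pd.DataFrame({"realized_mean": mean, "breadth_20": breadth,
                               "variant_loss": 1 - breadth})
        res = CoverageCurveModel(series).fit()
        assert res.m0 == pytest.approx(m0, rel=0.15)
        assert res.tau == pytest.approx(tau, rel=0.15)
        assert res.exp_r2 > 0.95
        assert "r^2" in res.summary()

    def test_degenerate_series_reports_nan(self):
        series = pd.DataFrame({"realized_mean": [20, 30, 40, 50],
                               "breadth_20": [0.8] * 4,
                               "variant_loss": [0.1] * 4})
        res = fit_coverage_curves(series)
        assert np.isnan(res.exp_r2) and np.isnan(res.linear_r2)

    def test_too_few_levels_rejected(self):
        series = pd.DataFrame({"realized_mean": [20, 30], "breadth_20": [0.5, 0.6],
                               "variant_loss": [0.2, 0.1]})
        with pytest.raises(ValueError):
            CoverageCurveModel(series)


class TestQuantiles:
    def test_summary_quantiles_match_sorted_oracle(self, rng):
        vals = rng.random(100) * 50
        q1 = np.quantile(vals, 0.25)
        q3 = np.quantile(vals, 0.75)
        assert q1 == pytest.approx(quantile_oracle(vals, 0.25))
        assert q3 == pytest.approx(quantile_oracle(vals, 0.75))
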