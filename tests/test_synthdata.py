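"""The synthetic cohort generator: determinism, reference texture, region
structure, truth composition, error structure and depth behaviour."""

import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ampliqc.covstats import region_depth_summary
from ampliqc.synthdata import (SimConfig, amplicon_weights, make_callset,
                               make_depth_and_reads, make_reference,
                               make_region_sets, make_truth_variants,
                               simulate_cohort, truth_composition,
                               write_fasta)


def count_homopolymers(seq, min_len=6):
    return sum(1 for m in re.finditer(r"(A+|C+|G+|T+)", seq)
               if len(m.group()) >= min_len)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(fn_rate_snp=1.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_truth_snps=-1)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=0)

    def test_tiny_genome_rejected_by_reference(self):
        with pytest.raises(ValueError):
            make_reference(SimConfig(genome_length=5000, n_exons=2))

    def test_oversized_exons_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(exon_length_bounds=(60, 2000))


class TestReference:
    def test_same_seed_identical_sequence(self, small_cfg):
        ref1, _ = make_reference(small_cfg)
        ref2, _ = make_reference(small_cfg)
        assert ref1 == ref2

    def test_different_seed_differs(self, small_cfg):
        other = SimConfig(**{**small_cfg.__dict__, "seed": small_cfg.seed + 1})
        assert make_reference(other)[0] != make_reference(small_cfg)[0]

    def test_planted_homopolymers_found_by_scan(self, small_cfg):
        ref, layout = make_reference(small_cfg)
        planted = len(layout.homopolymers)
        assert planted > 0
        assert count_homopolymers(ref["chr1"]) >= planted

    def test_gc_blocks_match_designated_class(self):
        cfg = SimConfig(seed=3, genome_length=220_000, n_exons=240,
                        gc_block_spec={"high": 0.15, "low": 0.1})
        ref, layout = make_reference(cfg)
        seq = ref["chr1"]
        for (s, e, _name, _i), cls in zip(layout.amplicons,
                                          layout.amplicon_class):
            gc = sum(seq[p] in "GC" for p in range(s, e)) / (e - s)
            if cls == "high":
                assert gc > 0.75
            elif cls == "low":
                assert gc < 0.25

    def test_fasta_round_trip(self, small_cfg, tmp_path):
        import pyfaidx
        ref, _ = make_reference(small_cfg)
        path = tmp_path / "r.fa"
        write_fasta(ref, path)
        fa = pyfaidx.Fasta(str(path))
        assert str(fa["chr1"][:]) == ref["chr1"]


class TestRegionSets:
    def test_amplicon_lengths_in_configured_range(self, small_cfg):
        bundle = make_region_sets(small_cfg)
        lo, hi = small_cfg.amplicon_length_range
        for _c, s, e, _n in bundle.amplicons:
            assert lo <= e - s <= hi

    def test_every_exon_fully_tiled_by_amplicons(self, small_cfg):
        bundle = make_region_sets(small_cfg)
        # per-base oracle: every CDS base inside the amplicon footprint
        amp_bases = {p for _c, s, e, _n in bundle.amplicons
                     for p in range(s, e)}
        for iv in bundle.cds:
            for p in range(iv.start, iv.end):
                assert p in amp_bases

    def test_exons_tiled_by_one_or_two_amplicons(self, small_cfg):
        from ampliqc.synthdata import _layout
        layout = _layout(small_cfg)
        counts = {}
        for *_ignore, exon_idx in layout.amplicons:
            counts[exon_idx] = counts.get(exon_idx, 0) + 1
        assert set(counts.values()) <= {1, 2}

    def test_deterministic(self, small_cfg):
        b1 = make_region_sets(small_cfg)
        b2 = make_region_sets(small_cfg)
        assert b1.targets == b2.targets and b1.cds == b2.cds


class TestTruth:
    def test_composition_scaling(self):
        assert truth_composition(1000) == (980, 20)
        assert truth_composition(16136) == (15811, 325)

    def test_requested_counts_and_membership(self, small_cfg, small_cohort):
        truth = small_cohort.truth
        n_snp = sum(1 for v in truth if not v.is_indel)
        assert n_snp == small_cfg.n_truth_snps
        assert len(truth) - n_snp == small_cfg.n_truth_indels
        ev = small_cohort.regions.evaluation
        assert all(ev.contains(v.chrom, v.pos - 1) for v in truth)

    def test_deterministic_vcf_bytes(self, small_cfg, tmp_path):
        from ampliqc.vcfnorm import write_vcf
        ref, _ = make_reference(small_cfg)
        bundle = make_region_sets(small_cfg)
        contigs = {c: len(s) for c, s in ref.items()}
        paths = []
        for i in (1, 2):
            truth = make_truth_variants(small_cfg, ref, bundle)
            p = tmp_path / f"t{i}.vcf"
            write_vcf(truth, p, contigs)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_too_many_variants_rejected(self):
        cfg = SimConfig(seed=2, genome_length=40_000, n_exons=30,
                        n_truth_snps=20_000, n_truth_indels=10)
        ref, _ = make_reference(cfg)
        bundle = make_region_sets(cfg)
        with pytest.raises(ValueError):
            make_truth_variants(cfg, ref, bundle)


class TestDepthAndReads:
    def test_realized_mean_within_ten_percent(self, small_cfg, small_cohort):
        for track in small_cohort.depth.values():
            s = region_depth_summary(track, small_cohort.regions.targets)
            assert s.mean_coverage == pytest.approx(
                small_cfg.mean_coverage, rel=0.10)

    def test_no_bias_limit_chi_square(self):
        cfg = SimConfig(seed=9, genome_length=220_000, n_exons=240,
                        gc_dropout_strength=0.0, amplicon_dispersion_sigma=0.0,
                        mean_coverage=150.0)
        bundle = make_region_sets(cfg)
        reads, _track = make_depth_and_reads(cfg, bundle, 0)
        counts = reads.groupby("start").size()
        by_start = {s: n for s, n in counts.items()}
        observed = np.array([by_start.get(s, 0)
                             for _c, s, _e, _n in bundle.amplicons])
        expected = np.full(len(observed), observed.sum() / len(observed))
        _chi, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_high_gc_dropout_lowers_median_depth(self):
        cfg = SimConfig(seed=9, genome_length=220_000, n_exons=240,
                        gc_block_spec={"high": 0.15, "low": 0.1})
        bundle = make_region_sets(cfg)
        _reads, track = make_depth_and_reads(cfg, bundle, 0)
        med = {}
        for cls in ("high", "mid"):
            depths = [track.mean_over(c, s, e)
                      for c, s, e, n in bundle.amplicons
                      if bundle.amplicon_class[n] == cls]
            med[cls] = np.median(depths)
        assert med["high"] < med["mid"]

    def test_bad_mean_coverage_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mean_coverage=0.0)


class TestCallsets:
    def test_zero_error_rates_reproduce_truth(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__,
                           "fn_rate_snp": 0.0, "fn_rate_indel": 0.0,
                           "fp_per_sample_snp": 0, "fp_per_sample_indel": 0,
                           "n_samples": 1})
        cohort = simulate_cohort(cfg, emit_reads=False)
        cs = cohort.callsets["S00"]
        call_keys = {(r.chrom, r.pos, r.ref, r.alts[0]) for r in cs.records}
        truth_keys = {v.key for v in cohort.truth}
        assert call_keys == truth_keys
        assert cs.fn.empty

    def test_fn_rate_within_binomial_band(self):
        # pool FN draws over many independent samples
        cfg = SimConfig(seed=21, genome_length=220_000, n_exons=240,
                        n_truth_snps=500, n_truth_indels=0, n_samples=10,
                        fp_per_sample_snp=0, fp_per_sample_indel=0,
                        fn_rate_snp=0.05)
        cohort = simulate_cohort(cfg, emit_reads=False)
        n_fn = sum(len(cs.fn) for cs in cohort.callsets.values())
        n_draws = 10 * 500
        lo, hi = stats.binom.interval(0.99, n_draws, 0.05)
        assert lo <= n_fn <= hi

    def test_conservation_per_sample(self, small_cohort):
        n_truth = len(small_cohort.truth)
        for cs in small_cohort.callsets.values():
            n_tp = (cs.labels.label == "tp").sum()
            assert n_tp + len(cs.fn) == n_truth

    def test_fp_annotations_lower_than_tp(self, small_cohort):
        lab = small_cohort.labels
        tp = lab[lab.label == "tp"]
        fp = lab[lab.label == "fp"]
        assert fp["GQ"].median() < tp["GQ"].median()
        assert fp["QUAL"].median() < tp["QUAL"].median()
        assert fp["FAO"].median() < tp["FAO"].median()
        assert fp["STB"].median() > tp["STB"].median()
        fpi = fp[fp.variant_class == "indel"]
        tpi = tp[tp.variant_class == "indel"]
        assert fpi["HRUN"].median() > tpi["HRUN"].median()

    def test_multiallelic_fp_indels_have_three_alts(self, small_cohort):
        lab = small_cohort.labels
        multi = lab[(lab.label == "fp") & (lab.n_original_alts >= 3)]
        assert (multi.variant_class == "indel").all()
        # raw records: multiallelic lines carry >= 3 alts
        for cs in small_cohort.callsets.values():
            for rec in cs.records:
                if len(rec.alts) > 1:
                    assert len(rec.alts) >= 3

    def test_cohort_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=4, genome_length=220_000, n_exons=240,
                        n_truth_snps=100, n_truth_indels=20, n_samples=2,
                        fp_per_sample_snp=15, fp_per_sample_indel=8)
        files = {}
        for run in ("a", "b"):
            out = tmp_path / run
            simulate_cohort(cfg, outdir=out, emit_reads=True)
            files[run] = {p.name: p.read_bytes()
                          for p in sorted(out.iterdir())}
        assert files["a"].keys() == files["b"].keys()
        for name in files["a"]:
            assert files["a"][name] == files["b"][name], name

    def test_sample_collision_rejected(self, small_cohort, small_cfg):
        # distinct samples must carry independent draws: identical ids would
        # silently overwrite callsets, so the driver keys them uniquely
        assert len(small_cohort.callsets) == small_cfg.n_samples
        ids = [cs.sample_id for cs in small_cohort.callsets.values()]
        assert len(set(ids)) == len(ids)
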