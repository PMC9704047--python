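"""Hyper-editing detector: transform, alignment, screens, clusters, enrichment."""

import numpy as np
import pandas as pd
import pytest

from editdev import _seq, hyper, synth
from editdev.config import FilterConfig
from editdev.intervals import AnnotationSet


def q(n, phred=37):
    return np.full(n, phred, dtype=np.int16)


@pytest.fixture(scope="module")
def ref20k():
    rng = np.random.default_rng(77)
    return {"chr1": rng.integers(0, 4, size=20_000).astype(np.uint8)}


class TestTransform:
    def test_a_becomes_g(self):
        assert hyper.transform_str("AAGCT") == "GGGCT"

    def test_a_free_sequence_unchanged(self):
        assert hyper.transform_str("GGCCTT") == "GGCCTT"

    def test_idempotent(self):
        once = hyper.transform_str("ACGTACGT")
        assert hyper.transform_str(once) == once

    def test_other_substitution_types(self):
        assert hyper.transform_str("ACGT", "C", "T") == "ATGT"


class TestPrescreen:
    def test_mono_nucleotide_dropped(self, cfg):
        seq = "A" * 70 + "CGT" * 10
        assert hyper.prescreen_reads([("r", seq, q(100))], cfg) == []

    def test_low_mean_phred_dropped(self, cfg):
        seq = "ACGT" * 25
        assert hyper.prescreen_reads([("r", seq, q(100, 24))], cfg) == []

    def test_balanced_high_quality_kept(self, cfg):
        seq = "ACGT" * 25
        assert len(hyper.prescreen_reads([("r", seq, q(100))], cfg)) == 1

    def test_simple_repeat_dropped(self, cfg):
        seq = "ACG" * 30 + "TCAGTTAGAC"
        assert hyper.prescreen_reads([("r", seq, q(100))], cfg) == []

    def test_high_n_dropped(self, cfg):
        seq = "N" * 15 + "ACGT" * 21 + "A"
        assert hyper.prescreen_reads([("r", seq, q(100))], cfg) == []


def edit_read(ref, start, length, n_edits, rng, lo_frac=0.1, hi_frac=0.9):
    """Read slice with n_edits A->G edits planted in the central span."""
    codes = ref["chr1"][start:start + length].copy()
    window = np.arange(int(lo_frac * length), int(hi_frac * length))
    a_pos = window[codes[window] == _seq.A]
    chosen = rng.choice(a_pos, size=n_edits, replace=False)
    codes[chosen] = _seq.G
    return codes, np.sort(start + chosen)


class TestAligner:
    def test_unique_perfect_match_placed(self, cfg, ref20k):
        aligner = hyper.TransformedAligner(ref20k, cfg)
        codes = ref20k["chr1"][500:600].copy()
        read = aligner.place_read("r", codes, q(100))
        assert read is not None and read.start == 500 and read.strand == "+"
        assert read.n_mismatch == 0

    def test_edited_read_recovers_planted_sites(self, cfg, ref20k):
        rng = np.random.default_rng(1)
        aligner = hyper.TransformedAligner(ref20k, cfg)
        codes, sites = edit_read(ref20k, 3000, 100, 8, rng)
        read = aligner.place_read("r", codes, q(100))
        assert read.start == 3000
        np.testing.assert_array_equal(np.sort(read.edit_gpos), sites)

    def test_flipped_orientation_read_recovers_same_edits(self, cfg, ref20k):
        # the reverse complement of a plus-strand edited read still reports
        # plus-strand A-to-G sites at the same genomic positions
        rng = np.random.default_rng(2)
        aligner = hyper.TransformedAligner(ref20k, cfg)
        codes, sites = edit_read(ref20k, 7000, 100, 8, rng)
        read = aligner.place_read("r", _seq.revcomp(codes), q(100))
        assert read.start == 7000 and read.strand == "+"
        np.testing.assert_array_equal(np.sort(read.edit_gpos), sites)

    def test_minus_strand_edits_recovered_as_minus(self, cfg, ref20k):
        # T-to-C mismatches on the plus reference = A-to-G on the minus strand
        rng = np.random.default_rng(6)
        codes = ref20k["chr1"][9000:9100].copy()
        window = np.arange(10, 90)
        t_pos = window[codes[window] == _seq.T][:8]
        codes[t_pos] = _seq.C
        aligner = hyper.TransformedAligner(ref20k, cfg)
        read = aligner.place_read("r", codes, q(100))
        assert read.start == 9000 and read.strand == "-"
        np.testing.assert_array_equal(np.sort(read.edit_gpos), np.sort(9000 + t_pos))

    def test_identical_copies_fail_margin(self, cfg):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 4, size=5000).astype(np.uint8)
        base[3000:3100] = base[1000:1100]          # perfect duplicate
        ref = {"chr1": base}
        aligner = hyper.TransformedAligner(ref, cfg)
        codes, _ = edit_read(ref, 1000, 100, 8, rng)
        read = aligner.place_read("r", codes, q(100))
        assert read is not None and not read.passed
        assert read.fail_reason == "multimap"

    def test_margin_separates_divergent_copies(self, cfg):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 4, size=5000).astype(np.uint8)
        base[3000:3100] = base[1000:1100]
        # two decoy-only C->T differences: decoy A-to-G fraction 8/10 vs 8/8
        cpos = 3000 + np.flatnonzero(base[3000:3100] == _seq.C)[:2]
        base[cpos] = _seq.T
        ref = {"chr1": base}
        aligner = hyper.TransformedAligner(ref, cfg)
        codes, sites = edit_read(ref, 1000, 100, 8, rng)
        read = aligner.place_read("r", codes, q(100))
        assert read.passed and read.start == 1000
        np.testing.assert_array_equal(np.sort(read.edit_gpos), sites)

    def test_reference_cap_enforced(self, cfg):
        with pytest.raises(ValueError, match="desk-scale"):
            hyper.SeedIndex(np.zeros(hyper.MAX_REFERENCE_BP + 1, dtype=np.uint8),
                            cfg.seed_len)


class TestScreen:
    def _read(self, gpos, qpos, n_mismatch, L=100, codes=None, qual=None):
        hr = hyper.HyperRead("r", "chr1", 0, "+", np.asarray(gpos),
                             np.asarray(qpos), n_mismatch, True)
        codes = codes if codes is not None else np.tile(
            np.array([0, 1, 2, 3], dtype=np.uint8), L // 4)
        qual = qual if qual is not None else q(L)
        return hyper.screen_hyper_read(hr, codes, qual, FilterConfig())

    def test_six_edits_one_other_mismatch_passes(self):
        out = self._read(np.arange(6) * 10 + 20, np.arange(6) * 10 + 20, 7)
        assert out.passed

    def test_short_read_boundary_fraction_fails(self):
        # 50 bp read: 4 of 5 mismatches = 0.8, not > 0.8
        out = self._read([20, 25, 30, 35], [20, 25, 30, 35], 5, L=48)
        assert not out.passed and out.fail_reason == "frac_mismatch"

    def test_span_over_90_percent_fails_density(self):
        qpos = [2, 30, 50, 70, 97]
        out = self._read(qpos, qpos, 5)
        assert not out.passed and out.fail_reason == "density"

    def test_edits_confined_to_read_end_fail(self):
        qpos = [1, 5, 9, 13, 17]
        out = self._read(qpos, qpos, 5)
        assert not out.passed and out.fail_reason == "read_end"

    def test_too_few_edits_fail(self):
        out = self._read([30, 50, 70, 90], [30, 50, 70, 90], 4)
        assert not out.passed and out.fail_reason == "frac_len"

    def test_low_quality_edits_do_not_count(self):
        qual = q(100)
        qpos = np.arange(6) * 10 + 20
        qual[qpos] = 29      # below the Phred >= 30 site cutoff
        out = self._read(qpos, qpos, 7, qual=qual)
        assert not out.passed and out.fail_reason == "frac_len"


class TestClusters:
    def _read(self, gpos, strand="+"):
        gpos = np.asarray(gpos)
        return hyper.HyperRead("r", "chr1", int(gpos.min()), strand, gpos,
                               gpos - gpos.min(), len(gpos), True)

    def test_extension_by_mean_spacing(self, cfg):
        clusters, site_set = hyper.merge_hyper_clusters([self._read([100, 110, 120])])
        (cl,) = clusters
        assert (cl.interval.start, cl.interval.end) == (90, 131)
        assert cl.n_sites == 3 and cl.mean_spacing == 10.0
        assert site_set == {("chr1", p, "+") for p in (100, 110, 120)}

    def test_overlapping_clusters_merged(self, cfg):
        reads = [self._read([100, 110, 120]), self._read([128, 140, 152])]
        clusters, _ = hyper.merge_hyper_clusters(reads)
        (cl,) = clusters
        assert (cl.interval.start, cl.interval.end) == (90, 165)
        assert cl.read_support == 2

    def test_single_site_extends_by_zero(self, cfg):
        (cl,), _ = hyper.merge_hyper_clusters([self._read([500])])
        assert (cl.interval.start, cl.interval.end) == (500, 501)

    def test_strands_never_merge(self, cfg):
        reads = [self._read([100, 110]), self._read([105, 115], strand="-")]
        clusters, _ = hyper.merge_hyper_clusters(reads)
        assert len(clusters) == 2

    def test_masked_site_removed(self, cfg):
        ann = AnnotationSet()
        ann.variant_maf[("chr1", 110)] = 0.3
        clusters, site_set = hyper.merge_hyper_clusters(
            [self._read([100, 110, 120])], ann, cfg)
        assert ("chr1", 110, "+") not in site_set
        assert clusters[0].n_sites == 2

    def test_private_genomic_call_removed(self, cfg):
        _, site_set = hyper.merge_hyper_clusters(
            [self._read([100, 110, 120])], None, cfg,
            sample_variant_positions={("chr1", 120)})
        assert ("chr1", 120, "+") not in site_set


class TestSignal:
    def test_arithmetic(self):
        assert hyper.normalized_hyper_signal(5000, 2_500_000_000).signal == 2.0

    def test_zero_sites(self):
        assert hyper.normalized_hyper_signal(0, 10**6).signal == 0.0

    def test_scale_invariance(self):
        a = hyper.normalized_hyper_signal(100, 10**7).signal
        b = hyper.normalized_hyper_signal(200, 2 * 10**7).signal
        assert a == b

    def test_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            hyper.normalized_hyper_signal(10, 0)


class TestDetectorEndToEnd:
    def _records(self, reads):
        return [(f"r{i}", _seq.decode(c), q(c.size)) for i, c in enumerate(reads)]

    def test_revcomp_input_reproduces_site_set(self, cfg, ref20k):
        rng = np.random.default_rng(9)
        reads = [edit_read(ref20k, 1000 + 800 * i, 100, 9, rng)[0]
                 for i in range(5)]
        fwd = hyper.detect_hyper_reads(self._records(reads), ref20k, cfg)
        rev = hyper.detect_hyper_reads(
            self._records([_seq.revcomp(c) for c in reads]), ref20k, cfg)
        sites_f = {(r.chrom, int(p)) for r in fwd if r.passed for p in r.edit_gpos}
        sites_r = {(r.chrom, int(p)) for r in rev if r.passed for p in r.edit_gpos}
        assert sites_f and sites_f == sites_r

    def test_other_substitution_screen_empty_on_a2g_reads(self, cfg, ref20k):
        rng = np.random.default_rng(10)
        reads = [edit_read(ref20k, 2000 + 900 * i, 100, 9, rng)[0]
                 for i in range(5)]
        n_prescreened = len(hyper.prescreen_reads(self._records(reads), cfg))
        a2g = hyper.detect_hyper_reads(self._records(reads), ref20k, cfg)
        assert sum(r.passed for r in a2g) == n_prescreened >= 4
        c2t = hyper.detect_hyper_reads(self._records(reads), ref20k, cfg,
                                       substitution=("C", "T"))
        assert sum(r.passed for r in c2t) == 0

    def test_planted_antisense_region_reports_minus_strand(self, cfg,
                                                           small_reference,
                                                           tmp_path):
        """Reads simulated from a minus-strand hyper region come back as
        A-to-G on the annotated strand (T-to-C on the reference plus strand)."""
        minus = [iv for iv, fam in small_reference.annotation.repeats
                 if fam == "Alu" and iv.strand == "-"]
        region = minus[0]
        cohort = synth.simulate_cohort(2, 2, seed=55).iloc[:1]
        truth = synth.planted_matrix_truth(n_null=0)
        truth.hyper_regions = pd.DataFrame([{
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "strand": "-", "p_edit": 0.35}])
        sim = synth.simulate_reads(small_reference, truth, cohort, tmp_path,
                                   coverage=5, seed=55, hyper_coverage=6)
        from editdev import seqio
        ref = {small_reference.chrom: small_reference.codes}
        reads = hyper.detect_hyper_reads(
            seqio.read_fastq(sim.fastq_paths[cohort.index[0]]), ref, cfg)
        passed = [r for r in reads if r.passed]
        assert passed
        assert {r.strand for r in passed} == {"-"}
        # recovered positions are reference-strand T (transcript-strand A)
        for r in passed:
            assert (ref["chr1"][r.edit_gpos] == _seq.T).all()


class TestGeneEnrichment:
    def _cohort(self, n=20):
        return synth.simulate_cohort(n // 2, n // 2, seed=13)

    def test_planted_postnatal_counts_significant(self, cfg):
        cohort = self._cohort(40)
        rng = np.random.default_rng(14)
        post = (cohort["epoch"] == "postnatal").to_numpy()
        counts = pd.DataFrame(
            {s: {"geneX": (rng.poisson(9) if post[i] else rng.poisson(1)),
                 "geneY": rng.poisson(3)}
             for i, s in enumerate(cohort.index)})
        res = hyper.gene_hyper_enrichment(counts, cohort, [], cfg)
        assert res.loc["geneX", "beta_postnatal"] > 0
        assert res.loc["geneX", "p_adj"] < 0.01
        assert res.loc["geneY", "p"] > res.loc["geneX", "p"]

    def test_identical_counts_give_null_effect(self, cfg):
        cohort = self._cohort(20)
        counts = pd.DataFrame({s: {"geneZ": 4.0, "geneW": 2.0} for s in cohort.index})
        res = hyper.gene_hyper_enrichment(counts, cohort, [], cfg)
        assert res["skipped"].all()

    def test_undetected_gene_filtered(self, cfg):
        cohort = self._cohort(20)
        counts = pd.DataFrame({s: {"rare": 0.0} for s in cohort.index})
        counts.iloc[0, 0] = 1.0
        res = hyper.gene_hyper_enrichment(counts, cohort, [], cfg)
        assert "rare" not in res.index
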