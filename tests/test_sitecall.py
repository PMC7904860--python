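"""Site calling: cut-geometry inversion, reference validation,
deduplication and SNP-based allele assignment."""

import numpy as np
import pandas as pd
import pysam
import pytest

import strandmeth as sm
from strandmeth import io as smio
from strandmeth.pipeline import simulate_and_call
from strandmeth.sitecall import assign_allele, call_sites, dedup


def write_sam(tmp_path, reference, records):
    """records: (qname, flag, chrom, pos0, seq, tags)"""
    header = smio.sam_header({c: len(s) for c, s in reference.items()})
    path = tmp_path / "reads.sam"
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for qname, flag, chrom, pos0, seq, tags in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = fh.get_tid(chrom)
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            for tag, val in tags.items():
                a.set_tag(tag, val)
            fh.write(a)
    return str(path)


BASE_TAGS = {"CB": "cellA", "RX": "AAA"}


class TestCallGeometry:
    def test_minus_read_implies_plus_strand_site_16_upstream(self, tmp_path):
        # reference with C at 10, G at 11 (CpG); minus-strand read whose
        # 5' genomic end sits at 26
        ref = {"chr1": "A" * 10 + "CG" + "A" * 28}
        seq_fwd = ref["chr1"][7:27]  # covers 7..26, rightmost base = 26
        sam = write_sam(tmp_path, ref, [("r1", 16, "chr1", 7, seq_fwd, BASE_TAGS)])
        calls, stats = call_sites(sam, ref)
        assert len(calls) == 1
        c = calls.iloc[0]
        assert (c.pos0, c.strand, c.context) == (10, "+", "CpG")
        assert stats.n_off_geometry == 0

    def test_plus_read_implies_minus_strand_site_16_downstream(self, tmp_path):
        # minus-strand C at 116 (reference G) preceded on the reference
        # by T at 115 -> minus-strand context CpA
        ref = {"chr1": "A" * 115 + "TG" + "A" * 43}
        seq_fwd = ref["chr1"][100:120]  # plus-strand read, 5' end at 100
        sam = write_sam(tmp_path, ref, [("r1", 0, "chr1", 100, seq_fwd, BASE_TAGS)])
        calls, _ = call_sites(sam, ref)
        assert len(calls) == 1
        c = calls.iloc[0]
        assert (c.pos0, c.strand, c.context) == (116, "-", "CpA")

    def test_non_cytosine_candidate_counts_off_geometry(self, tmp_path):
        ref = {"chr1": "A" * 60}  # no cytosine anywhere
        sam = write_sam(tmp_path, ref, [("r1", 0, "chr1", 10, "A" * 20, BASE_TAGS)])
        calls, stats = call_sites(sam, ref)
        assert calls.empty
        assert stats.n_off_geometry == 1

    def test_candidate_outside_chromosome_skipped(self, tmp_path):
        ref = {"chr1": "A" * 40}
        # plus read at 30: candidate 46 beyond the 40-bp chromosome
        sam = write_sam(tmp_path, ref, [("r1", 0, "chr1", 30, "A" * 10, BASE_TAGS)])
        calls, stats = call_sites(sam, ref)
        assert calls.empty
        assert stats.n_out_of_range == 1


class TestDedup:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=sm.sitecall.CALL_COLUMNS)

    def test_same_umi_collapses_with_support(self):
        row = ("cellA", "chr1", 10, "+", "CpG", "unknown", "AAA", 1)
        out = dedup(self._calls([row, row, row]))
        assert len(out) == 1
        assert out.support.iloc[0] == 3

    def test_distinct_umis_stay_separate(self):
        r1 = ("cellA", "chr1", 10, "+", "CpG", "unknown", "AAA", 1)
        r2 = ("cellA", "chr1", 10, "+", "CpG", "unknown", "CCC", 1)
        assert len(dedup(self._calls([r1, r2]))) == 2

    def test_idempotent(self):
        rows = [("cellA", "chr1", 10, "+", "CpG", "unknown", "AAA", 1),
                ("cellB", "chr1", 10, "+", "CpG", "unknown", "AAA", 1),
                ("cellA", "chr1", 10, "+", "CpG", "unknown", "AAA", 1)]
        once = dedup(self._calls(rows))
        twice = dedup(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSimulatorRoundTrip:
    def test_called_sites_equal_truth_exactly(self, small_genome, tmp_path):
        p = sm.SimParams(capture_eff=1.0, dup_rate=0.0, h_frac=0.2,
                         d_cpa=0.05, n_cells=1, seed=3)
        calls, truth_frags, stats = simulate_and_call(
            small_genome, p, str(tmp_path))
        called = set(zip(calls.chrom, calls.pos0, calls.strand))
        truth = {(f.chrom, f.mC_pos0, f.mC_strand) for f in truth_frags[0]}
        assert called == truth
        assert stats.n_off_geometry == 0

    def test_dedup_recovers_distinct_molecules_with_duplicates(
            self, small_genome, tmp_path):
        p = sm.SimParams(capture_eff=1.0, dup_rate=2.0, n_cells=1, seed=3)
        calls, truth_frags, _ = simulate_and_call(small_genome, p, str(tmp_path))
        keys = {(f.chrom, f.mC_pos0, f.mC_strand, f.umi) for f in truth_frags[0]}
        assert len(calls) == len(keys)
        # every duplicate group collapsed: support sums to the read count
        assert calls.support.sum() > len(calls)

    def test_context_partition_is_exhaustive(self, small_genome, tmp_path):
        p = sm.SimParams(capture_eff=1.0, d_cpa=0.05, n_cells=1, seed=3)
        calls, _, _ = simulate_and_call(small_genome, p, str(tmp_path))
        assert set(calls.context) <= {"CpG", "CpA", "CpC", "CpT"}
        assert calls.context.value_counts().sum() == len(calls)


class TestAssignAllele:
    def test_read_covering_alt_snp_gives_allele2(self, tmp_path):
        ref = {"chr1": "A" * 84 + "CG" + "A" * 114}
        # minus-strand read spans 81..100 (5' end 100 -> site at 84)
        seq = list(ref["chr1"][81:101])
        seq[90 - 81] = "T"  # alt base at SNP position 90
        sam = write_sam(tmp_path, ref,
                        [("r1", 16, "chr1", 81, "".join(seq), BASE_TAGS)])
        calls, _ = call_sites(sam, ref)
        calls = dedup(calls)
        out = assign_allele(calls, sam, [("chr1", 90, "A", "T")], ref)
        assert out.allele.iloc[0] == "allele2"

    def test_read_covering_ref_snp_gives_allele1(self, tmp_path):
        ref = {"chr1": "A" * 84 + "CG" + "A" * 114}
        seq = ref["chr1"][81:101]
        sam = write_sam(tmp_path, ref, [("r1", 16, "chr1", 81, seq, BASE_TAGS)])
        calls, _ = call_sites(sam, ref)
        calls = dedup(calls)
        out = assign_allele(calls, sam, [("chr1", 90, "A", "T")], ref)
        assert out.allele.iloc[0] == "allele1"

    def test_no_covered_snp_stays_unknown(self, tmp_path):
        ref = {"chr1": "A" * 84 + "CG" + "A" * 114}
        seq = ref["chr1"][81:101]
        sam = write_sam(tmp_path, ref, [("r1", 16, "chr1", 81, seq, BASE_TAGS)])
        calls, _ = call_sites(sam, ref)
        calls = dedup(calls)
        out = assign_allele(calls, sam, [("chr1", 150, "A", "T")], ref)
        assert out.allele.iloc[0] == "unknown"

    def test_mismatching_snp_dropped(self, tmp_path):
        ref = {"chr1": "A" * 84 + "CG" + "A" * 114}
        seq = ref["chr1"][81:101]
        sam = write_sam(tmp_path, ref, [("r1", 16, "chr1", 81, seq, BASE_TAGS)])
        calls, _ = call_sites(sam, ref)
        calls = dedup(calls)
        # SNP claims ref C at a position where the FASTA has A
        out = assign_allele(calls, sam, [("chr1", 90, "C", "T")], ref)
        assert out.allele.iloc[0] == "unknown"

    def test_simulated_cohort_assignment_rate_and_correctness(
            self, snp_genome, tmp_path):
        p = sm.SimParams(capture_eff=0.5, dup_rate=0.0, n_cells=4, seed=9)
        calls, truth_frags, _ = simulate_and_call(
            snp_genome, p, str(tmp_path), with_alleles=True)
        frag_allele = {}
        for cid, frs in truth_frags.items():
            for f in frs:
                frag_allele[(f"cell{cid}", f.chrom, f.mC_pos0,
                             f.mC_strand, f.umi)] = f.allele
        lab = {"allele1": 1, "allele2": 2}
        assigned = calls[calls.allele.isin(lab)]
        # coverage expectation: a read carries >= 1 SNP with prob
        # ~ 1 - (1 - snp_rate)^glen
        glen = 75 - 11
        expected = 1 - (1 - 0.01) ** glen
        rate = len(assigned) / len(calls)
        assert abs(rate - expected) < 0.15
        # accuracy of assignments vs truth (UMI-collided molecules, where
        # two alleles merged into one call, are not in the truth map)
        truth_vals = [frag_allele.get((r.cell, r.chrom, r.pos0, r.strand, r.umi))
                      for r in assigned.itertuples()]
        ok = sum(1 for t, a in zip(truth_vals, assigned.allele)
                 if t is not None and lab[a] == t)
        known = sum(1 for t in truth_vals if t is not None)
        assert known > 0
        assert ok / known > 0.99
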