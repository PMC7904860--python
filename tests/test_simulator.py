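"""Simulator unit and property tests: genome, methylome model, digest,
read emission and the hairpin dyad generator."""

import numpy as np
import pytest

import strandmeth as sm
from strandmeth.simulate import (
    STATE_5HMC,
    STATE_5MC,
    simulate_hairpin,
)
from conftest import single_site_genome, single_site_truth


class TestMakeGenome:
    def test_snp_count_matches_binomial_expectation(self):
        g = sm.make_genome(1, 10000, 0.5, 0.001, 7)
        expected, sd = 10.0, np.sqrt(10000 * 0.001 * 0.999)
        assert abs(len(g.snps) - expected) < 4 * sd

    def test_zero_snp_rate_gives_identical_haplotypes(self):
        g = sm.make_genome(1, 10000, 0.5, 0.0, 1)
        assert g.snps == []
        assert g.haplotype("chr1", 1) == g.haplotype("chr1", 2)

    def test_deterministic_for_fixed_seed(self):
        g1 = sm.make_genome(2, 1000, 0.4, 0.01, 7)
        g2 = sm.make_genome(2, 1000, 0.4, 0.01, 7)
        assert g1.chromosomes == g2.chromosomes
        assert g1.snps == g2.snps

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrom_len"):
            sm.make_genome(1, 100, 0.5, 0.0, 1)

    def test_variable_chromosome_lengths(self):
        g = sm.make_genome(3, [300, 400, 500], 0.5, 0.0, 2)
        assert [len(g.chromosomes[c]) for c in ("chr1", "chr2", "chr3")] == \
            [300, 400, 500]

    def test_snp_alt_differs_from_ref(self, snp_genome):
        for chrom, pos0, ref, alt in snp_genome.snps:
            assert ref != alt
            assert snp_genome.chromosomes[chrom][pos0] == ref


class TestMethylome:
    def _dyads(self, genome, truth, chrom, allele):
        """(plus_state, minus_state) arrays over the CpG dyads."""
        plus = truth.states[(chrom, allele, "+")]
        minus = truth.states[(chrom, allele, "-")]
        dyad_idx = np.flatnonzero(plus.context == "G")
        dyad_pos = plus.pos[dyad_idx]
        minus_idx = np.searchsorted(minus.pos, dyad_pos + 1)
        return plus.state[dyad_idx], minus.state[minus_idx]

    def test_full_maintenance_gives_symmetric_dyads(self, small_genome):
        p = sm.SimParams(m_parent=0.8, e_maint=1.0, h_frac=0.0, d_cpa=0.0, seed=3)
        truth = sm.assign_methylome(small_genome, p, 0)
        for chrom in small_genome.chrom_names:
            for allele in (1, 2):
                ps, ms = self._dyads(small_genome, truth, chrom, allele)
                assert np.array_equal(ps == STATE_5MC, ms == STATE_5MC)

    def test_no_maintenance_gives_hemimethylated_parental_dyads(self, small_genome):
        p = sm.SimParams(m_parent=0.8, e_maint=0.0, h_frac=0.0, d_cpa=0.0, seed=3)
        truth = sm.assign_methylome(small_genome, p, 0)
        for chrom in small_genome.chrom_names:
            for allele in (1, 2):
                ps, ms = self._dyads(small_genome, truth, chrom, allele)
                parental = truth.parental[(chrom, allele)]
                daughter = ms if parental == "+" else ps
                # daughter strand never methylated, parental carries it all
                assert not (daughter == STATE_5MC).any()
                assert ((ps == STATE_5MC) | (ms == STATE_5MC)).sum() > 0

    def test_maintenance_fraction_matches_e_maint(self):
        # ~1e4 dyads: symmetric fraction among parental-methylated dyads
        g = sm.make_genome(1, 170000, 0.5, 0.0, 5)
        p = sm.SimParams(m_parent=0.8, e_maint=0.9, h_frac=0.0, d_cpa=0.0, seed=9)
        truth = sm.assign_methylome(g, p, 0)
        n_sym = n_meth = 0
        for allele in (1, 2):
            ps, ms = self._dyads(g, truth, "chr1", allele)
            meth = (ps == STATE_5MC) | (ms == STATE_5MC)
            sym = (ps == STATE_5MC) & (ms == STATE_5MC)
            n_meth += meth.sum()
            n_sym += sym.sum()
        assert n_meth > 8000
        frac = n_sym / n_meth
        sd = np.sqrt(0.9 * 0.1 / n_meth)
        assert abs(frac - 0.9) < 4 * sd

    def test_parental_override_plants_strand(self, small_genome):
        p = sm.SimParams(m_parent=0.8, e_maint=0.0, h_frac=0.0, d_cpa=0.0, seed=3)
        parental = {(c, a): "-" for c in small_genome.chrom_names for a in (1, 2)}
        truth = sm.assign_methylome(small_genome, p, 0, parental=parental)
        assert truth.parental == parental
        for chrom in small_genome.chrom_names:
            for allele in (1, 2):
                ps, ms = self._dyads(small_genome, truth, chrom, allele)
                assert not (ps == STATE_5MC).any()


class TestDigest:
    def test_single_plus_strand_site_cut_16_downstream(self):
        g = single_site_genome(ctx_after_c="G", r_base="A")
        truth = single_site_truth(g, state=STATE_5MC)
        frags = sm.digest_mspji(g, truth, capture_eff=1.0)
        assert len(frags) == 1
        f = frags[0]
        assert f.cut_pos0 == 100 + 16
        assert f.mC_strand == "+"
        assert f.overhang_len == 4

    def test_5hmc_site_is_blocked_by_glucosylation(self):
        g = single_site_genome()
        truth = single_site_truth(g, state=STATE_5HMC)
        assert sm.digest_mspji(g, truth, capture_eff=1.0) == []

    def test_pyrimidine_at_plus3_is_not_recognised(self):
        # CNNT: T at the +3 recognition position -> no mCNNR site
        g = single_site_genome(r_base="T")
        truth = single_site_truth(g, state=STATE_5MC)
        assert sm.digest_mspji(g, truth, capture_eff=1.0) == []

    def test_cut_offset_exactly_16_for_all_fragments(self, small_genome):
        p = sm.SimParams(capture_eff=1.0, dup_rate=0.0, seed=4)
        truth = sm.assign_methylome(small_genome, p, 0)
        frags = sm.digest_mspji(small_genome, truth, capture_eff=1.0)
        assert frags
        for f in frags:
            off = f.cut_pos0 - f.mC_pos0 if f.mC_strand == "+" else f.mC_pos0 - f.cut_pos0
            assert off == 16

    def test_no_fragment_from_unmethylated_or_5hmc(self, small_genome):
        p = sm.SimParams(capture_eff=1.0, h_frac=0.3, seed=4)
        truth = sm.assign_methylome(small_genome, p, 0)
        frags = sm.digest_mspji(small_genome, truth, capture_eff=1.0)
        for f in frags:
            ss = truth.states[(f.chrom, f.allele, f.mC_strand)]
            idx = np.searchsorted(ss.pos, f.mC_pos0)
            assert ss.state[idx] == STATE_5MC


class TestEmitReads:
    def test_plus_strand_site_maps_to_minus_read_at_cut(self):
        g = single_site_genome()
        truth = single_site_truth(g)
        frags = sm.digest_mspji(g, truth, capture_eff=1.0)
        reads, dropped = sm.emit_reads(frags, g, read_len=40)
        assert dropped == []
        (r,) = reads
        assert r.reverse  # antisense to the plus-strand 5mC
        glen = 40 - 11
        # 5' genomic end of a reverse read is its rightmost base: the cut
        assert r.ref_start0 + glen - 1 == 116

    def test_read_prefix_is_umi_then_barcode(self):
        g = single_site_genome()
        truth = single_site_truth(g)
        frags = sm.digest_mspji(g, truth, capture_eff=1.0, cell_barcode="TTGGCCAA")
        reads, _ = sm.emit_reads(frags, g, read_len=40)
        r = reads[0]
        assert r.sequence[0:3] == r.umi
        assert r.sequence[3:11] == "TTGGCCAA"

    def test_dup_rate_zero_one_read_per_fragment(self, small_genome):
        p = sm.SimParams(capture_eff=1.0, dup_rate=0.0, seed=4, h_frac=0.0)
        truth = sm.assign_methylome(small_genome, p, 0)
        frags = sm.digest_mspji(small_genome, truth, capture_eff=1.0)
        reads, dropped = sm.emit_reads(frags, small_genome, read_len=75)
        assert len(reads) == len(frags) - len(dropped)

    def test_off_end_fragment_dropped(self):
        # plus-strand 5mC near the chromosome start: the reverse read's
        # leftward extension runs off the origin
        g = single_site_genome(c_pos=10, length=200)
        truth = single_site_truth(g, pos=10)
        frags = sm.digest_mspji(g, truth, capture_eff=1.0)
        assert len(frags) == 1
        reads, dropped = sm.emit_reads(frags, g, read_len=40)
        assert reads == [] and len(dropped) == 1

    def test_duplicates_share_umi_and_sequence(self, small_genome):
        p = sm.SimParams(capture_eff=1.0, dup_rate=3.0, seed=4)
        _, frags, reads = sm.simulate_cell_reads(small_genome, p, 0)
        by_serial = {}
        for r in reads:
            key = r.read_id.rsplit(".", 1)[0]
            by_serial.setdefault(key, []).append(r)
        assert any(len(v) > 1 for v in by_serial.values())
        for group in by_serial.values():
            assert len({(r.sequence, r.umi, r.ref_start0) for r in group}) == 1

    def test_simulation_deterministic_for_fixed_seed(self, small_genome):
        p = sm.SimParams(capture_eff=0.7, dup_rate=1.0, seed=11)
        _, f1, r1 = sm.simulate_cell_reads(small_genome, p, 0)
        _, f2, r2 = sm.simulate_cell_reads(small_genome, p, 0)
        assert f1 == f2
        assert [(x.read_id, x.sequence) for x in r1] == \
            [(x.read_id, x.sequence) for x in r2]


class TestSimulateHairpin:
    def test_full_maintenance_all_symmetric(self):
        obs = simulate_hairpin(5000, 0.8, 1.0, 0.0, seed=1)
        meth = obs.any(axis=1)
        assert (obs[meth].sum(axis=1) == 2).all()

    def test_no_maintenance_all_hemi(self):
        obs = simulate_hairpin(5000, 0.8, 0.0, 0.0, seed=1)
        meth = obs.any(axis=1)
        assert (obs[meth].sum(axis=1) == 1).all()

    def test_partial_maintenance_fraction(self):
        obs = simulate_hairpin(100_000, 0.8, 0.7, 0.0, seed=2)
        meth = obs.any(axis=1)
        frac = (obs[meth].sum(axis=1) == 2).mean()
        sd = np.sqrt(0.7 * 0.3 / meth.sum())
        assert abs(frac - 0.7) < 4 * sd
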