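"""Ground-truth integrity of the synthetic-data generator."""

import math

import numpy as np
import pytest

from asmpipe import simdata
from asmpipe.seq import hamming_identity, revcomp


class TestSimulateDiploid:
    def test_zero_het_rate_gives_identical_haplotypes(self):
        g = simdata.simulate_diploid(1, 2000, 0.0, seed=1)
        assert g.haplotype_b == g.haplotype_a
        assert g.truth_snps == []

    def test_snp_count_within_binomial_bounds(self):
        g = simdata.simulate_diploid(1, 1_000_000, 0.004, seed=1)
        expected = 4000
        spread = 3 * math.sqrt(expected * 0.996)
        assert abs(len(g.truth_snps) - expected) <= spread

    def test_snps_recorded_faithfully(self, small_genome):
        for chrom, pos, a, b in small_genome.truth_snps[:50]:
            assert small_genome.haplotype_a[chrom][pos] == a
            assert small_genome.haplotype_b[chrom][pos] == b
            assert a != b

    def test_planted_tandem_array_is_verbatim(self):
        g = simdata.simulate_diploid(
            1, 10_000, 0.0, repeat_spec=[("chr1", 1000, "TTAGGG", 100)], seed=2)
        assert g.haplotype_a["chr1"][1000:1600] == "TTAGGG" * 100
        assert g.repeat_tracks == [("chr1", 1000, "TTAGGG", 100)]

    def test_oversized_repeat_rejected(self):
        with pytest.raises(ValueError, match="exceeds chromosome length"):
            simdata.simulate_diploid(
                1, 1000, 0.0, repeat_spec=[("chr1", 900, "TTAGGG", 100)], seed=0)

    def test_determinism_and_seed_sensitivity(self):
        a = simdata.simulate_diploid(1, 2000, 0.004, seed=5)
        b = simdata.simulate_diploid(1, 2000, 0.004, seed=5)
        c = simdata.simulate_diploid(1, 2000, 0.004, seed=6)
        assert a.haplotype_a == b.haplotype_a and a.truth_snps == b.truth_snps
        assert c.haplotype_a != a.haplotype_a


class TestSimulateReads:
    def test_zero_coverage_is_empty(self, small_genome):
        assert simdata.simulate_reads(small_genome, 0, 100, 0.0, seed=1) == []

    def test_error_free_homozygous_reads_are_substrings(self):
        g = simdata.simulate_diploid(1, 5000, 0.0, seed=3)
        reads = simdata.simulate_reads(g, 30, 100, 0.0, seed=4)
        chrom = g.haplotype_a["chr1"]
        for _, s in reads[:200]:
            assert s in chrom or revcomp(s) in chrom

    def test_coverage_accounting(self):
        g = simdata.simulate_diploid(1, 1_000_000, 0.004, seed=1)
        reads = simdata.simulate_reads(g, 36, 100, 0.005, seed=2)
        total = sum(len(s) for _, s in reads)
        assert 35.64e6 <= total <= 36.36e6

    def test_read_longer_than_chromosome_rejected(self):
        g = simdata.simulate_diploid(1, 1000, 0.0, seed=1)
        with pytest.raises(ValueError, match="read_length"):
            simdata.simulate_reads(g, 1, 2000, 0.0, seed=1)

    def test_substitution_error_rate_realized(self):
        g = simdata.simulate_diploid(1, 200_000, 0.0, seed=9)
        reads = simdata.simulate_reads(g, 5, 100, 0.01, seed=10)
        chrom = g.haplotype_a["chr1"]
        mismatch_pct = placed = 0
        for _, s in reads[:2000]:
            hit = _locate(chrom, s)
            if hit is None:
                continue  # rare: no error-free anchor seed in the read
            probe, pos = hit
            mismatch_pct += 100.0 - hamming_identity(probe, chrom[pos:pos + 100])
            placed += 1
        rate = mismatch_pct / placed / 100.0
        assert placed > 1800
        assert abs(rate - 0.01) < 0.003


def _locate(chrom, read):
    """Place a read on the forward strand via an error-free anchor seed."""
    for probe in (read, revcomp(read)):
        for off in (0, 37, 74):
            p = chrom.find(probe[off:off + 26])
            if p >= 0 and 0 <= p - off <= len(chrom) - 100:
                return probe, p - off
    return None


class TestFragmentAssembly:
    def test_no_breaks_yields_whole_chromosomes(self, small_genome):
        contigs, layout = simdata.fragment_assembly(small_genome, 0, (200, 500),
                                                    seed=1)
        assert len(contigs) == 2
        for chrom, placements in layout.contig_order.items():
            (cid, orient, start, end), = placements
            assert contigs[cid] == small_genome.haplotype_a[chrom]
            assert (orient, start, end) == ("+", 0, 50_000)

    def test_overlap_bookkeeping(self, small_genome):
        contigs, layout = simdata.fragment_assembly(small_genome, 3, (200, 200),
                                                    seed=2)
        for chrom, placements in layout.contig_order.items():
            assert len(placements) == 4
            ids = [cid for cid, *_ in placements]
            total = sum(len(contigs[c]) for c in ids)
            assert total == 50_000 + 3 * 200

    def test_orientation_flips_recorded(self, small_genome):
        contigs, layout = simdata.fragment_assembly(
            small_genome, 3, (200, 500), seed=3, flip_fraction=1.0)
        for chrom, placements in layout.contig_order.items():
            for cid, orient, start, end in placements:
                assert orient == "-"
                assert contigs[cid] == revcomp(
                    small_genome.haplotype_a[chrom][start:end])

    def test_reconstruction_roundtrip(self, small_genome):
        """Trimming planted overlaps and concatenating reproduces the
        chromosome byte-for-byte, flips included."""
        contigs, layout = simdata.fragment_assembly(
            small_genome, 5, (200, 500), seed=4, flip_fraction=0.5)
        ov = {left: n for left, _, n in layout.planted_overlaps}
        for chrom, placements in layout.contig_order.items():
            parts = []
            for i, (cid, orient, _, _) in enumerate(placements):
                piece = contigs[cid] if orient == "+" else revcomp(contigs[cid])
                if i < len(placements) - 1:
                    piece = piece[:-ov[cid]]
                parts.append(piece)
            assert "".join(parts) == small_genome.haplotype_a[chrom]

    def test_impossible_overlaps_rejected(self):
        g = simdata.simulate_diploid(1, 2000, 0.0, seed=1)
        with pytest.raises(ValueError):
            simdata.fragment_assembly(g, 10, (500, 900), seed=1)


class TestMutateReference:
    def test_identity_case_single_plus_block(self, small_genome):
        ref, blocks = simdata.mutate_reference(small_genome, seed=1)
        assert ref == small_genome.haplotype_a
        per_chrom = {b.query_id: b for b in blocks}
        assert len(blocks) == 2
        for chrom, b in per_chrom.items():
            assert (b.orientation, b.qstart, b.qend) == ("+", 0, 50_000)

    def test_single_inversion_block_map(self):
        g = simdata.simulate_diploid(1, 1_000_000, 0.0, seed=2)
        ref, blocks = simdata.mutate_reference(
            g, n_inversions=1, seed=3, segment_length=250_000)
        minus = [b for b in blocks if b.orientation == "-"]
        assert len(minus) == 1
        assert minus[0].qend - minus[0].qstart == 250_000
        spans = sorted((b.rstart, b.rend, b.orientation) for b in blocks)
        assert [s[2] for s in spans] == ["+", "-", "+"]
        # inverted reference segment is the reverse complement of the source
        b = minus[0]
        assert ref[b.ref_id][b.rstart:b.rend] == revcomp(
            g.haplotype_a[b.query_id][b.qstart:b.qend])

    def test_divergence_rate_realized(self):
        g = simdata.simulate_diploid(1, 100_000, 0.0, seed=4)
        ref, _ = simdata.mutate_reference(g, divergence=0.1, seed=5)
        ident = hamming_identity(ref["chr1"], g.haplotype_a["chr1"])
        assert abs(ident - 90.0) < 1.0

    def test_unplaceable_rearrangements_rejected(self):
        g = simdata.simulate_diploid(1, 50_000, 0.0, seed=6)
        with pytest.raises(ValueError):
            simdata.mutate_reference(g, n_inversions=1, segment_length=250_000)


class TestSimulateMarkers:
    def test_marker_is_exact_substring(self, small_genome, fragmented):
        contigs, layout = fragmented
        markers, truth = simdata.simulate_markers(layout, contigs, 1, 300, seed=1)
        t, = truth
        assert markers[t.marker_id] == contigs[t.contig_id][t.offset:t.offset + 300]
        assert t.linkage_group in small_genome.haplotype_a

    def test_marker_count_conservation(self, fragmented):
        contigs, layout = fragmented
        markers, truth = simdata.simulate_markers(layout, contigs, 100, 300, seed=2)
        assert len(markers) == len(truth) == 100
        lgs = {t.linkage_group for t in truth}
        assert lgs == {"chr1", "chr2"}

    def test_mutated_negative_control_below_identity_filter(self, fragmented):
        contigs, layout = fragmented
        markers, truth = simdata.simulate_markers(
            layout, contigs, 5, 300, seed=3, n_mutated=2, mutate_fraction=0.15)
        for t in truth[:2]:
            ref = contigs[t.contig_id][t.offset:t.offset + t.length]
            assert hamming_identity(markers[t.marker_id], ref) < 90.0

    def test_too_many_markers_rejected(self, fragmented):
        contigs, layout = fragmented
        with pytest.raises(ValueError, match="placeable"):
            simdata.simulate_markers(layout, contigs, 10 ** 9, 300, seed=1)
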