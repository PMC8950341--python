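"""Toy mapper: seeding, MAPQ-0 ties, SAM output, brute-force agreement."""

import pysam
import pytest

from refdup.alnqc import depth_profile
from refdup.reference_io import Genome, MaskInterval, mask_fasta
from refdup.simgen import make_random_genome, plant_duplicate, simulate_reads
from refdup.toymap import index_reference, map_read, map_reads, write_sam
from refdup._util import revcomp

from _oracles import brute_force_best_hits


@pytest.fixture(scope="module")
def dup_genome():
    """30 kb genome carrying an exact 2 kb duplicate of [10000, 12000)."""
    base = make_random_genome({"chrA": 30_000}, seed=11)
    ref, truth = plant_duplicate(base, ("chrA", 10_000, 12_000), "chrB", 0, 0.0, 12)
    return ref, truth


class TestIndexReference:
    def test_masked_region_generates_no_seeds(self):
        genome = make_random_genome({"c": 2000}, seed=5)
        masked = mask_fasta(genome, [MaskInterval("c", 500, 1500)])
        idx = index_reference(masked, k=21)
        inside = [
            pos
            for hits in idx.seeds.values()
            for _, pos in hits
            if 500 - 20 <= pos < 1500
        ]
        assert inside == []

    def test_indexed_positions_match_sequence(self):
        genome = make_random_genome({"c": 1000}, seed=5)
        idx = index_reference(genome, k=21)
        for kmer, hits in idx.seeds.items():
            for contig, pos in hits:
                assert genome[contig][pos : pos + 21] == kmer

    def test_duplicated_block_kmers_occur_twice(self, dup_genome):
        ref, truth = dup_genome
        idx = index_reference(ref, k=21)
        for off in range(0, 2000 - 21, 100):
            kmer = ref["chrB"][off : off + 21]
            assert len(idx.seeds[kmer]) >= 2


class TestMapRead:
    def test_unique_locus_read_maps_at_truth_with_mapq_60(self):
        genome = make_random_genome({"c": 5000}, seed=8)
        idx = index_reference(genome, k=21)
        aln = map_read("r", genome["c"][1000:1150], idx)
        assert (aln.contig, aln.pos, aln.strand, aln.mapq) == ("c", 1000, "+", 60)
        assert aln.mismatches == 0

    def test_reverse_complement_read_maps_to_minus_strand(self):
        genome = make_random_genome({"c": 5000}, seed=8)
        idx = index_reference(genome, k=21)
        aln = map_read("r", revcomp(genome["c"][1000:1150]), idx)
        assert (aln.pos, aln.strand, aln.mapq) == (1000, "-", 60)
        assert aln.seq == genome["c"][1000:1150]  # stored as aligned

    def test_read_inside_exact_duplicate_gets_mapq0_lowest_coordinate(self, dup_genome):
        ref, truth = dup_genome
        idx = index_reference(ref, k=21)
        read = ref["chrA"][10_500 : 10_650]
        aln = map_read("r", read, idx)
        assert aln.mapq == 0
        assert (aln.contig, aln.pos) == ("chrA", 10_500)  # smallest placement

    def test_one_diverged_site_separates_copies_with_mapq_20(self):
        base = make_random_genome({"chrA": 10_000}, seed=13)
        # copy with exactly one substitution inside the read's span
        ref, truth = plant_duplicate(base, ("chrA", 2_000, 4_000), "chrB", 0, 0.0, 14)
        seq = ref["chrB"]
        pos = 1_000
        swapped = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        ref = Genome(
            {"chrA": ref["chrA"], "chrB": seq[:pos] + swapped + seq[pos + 1 :]}
        )
        idx = index_reference(ref, k=21)
        read = ref["chrA"][2_950 : 3_100]  # overlaps the diverged site at chrA:3000
        aln = map_read("r", read, idx)
        assert (aln.contig, aln.pos) == ("chrA", 2_950)
        assert aln.mapq == 20  # best 0, second best 1
        assert aln.mismatches == 0

    def test_read_shorter_than_k_is_unmapped(self):
        genome = make_random_genome({"c": 1000}, seed=1)
        idx = index_reference(genome, k=21)
        assert not map_read("r", "ACGTACGT", idx).is_mapped

    def test_read_with_too_many_mismatches_is_unmapped(self):
        genome = make_random_genome({"c": 1000}, seed=1)
        idx = index_reference(genome, k=21)
        read = genome["c"][100:250]
        corrupted = read[:21] + "".join(
            {"A": "C", "C": "G", "G": "T", "T": "A"}[c] for c in read[21:60]
        ) + read[60:]
        assert not map_read("r", corrupted, idx, max_mismatches=8).is_mapped


class TestWriteSam:
    def test_mapped_read_round_trips_through_depth_profile(self, tmp_path):
        genome = make_random_genome({"c": 1000}, seed=2)
        idx = index_reference(genome, k=21)
        aln = map_read("r", genome["c"][100:250], idx)
        path = tmp_path / "a.sam"
        write_sam([aln], genome, str(path))
        profile = depth_profile(str(path), "c", 1000)
        assert profile.depth_mq_pass[100:250].sum() == 150
        assert profile.depth_mq_pass.sum() == 150

    def test_unmapped_read_sam_conventions(self, tmp_path):
        genome = make_random_genome({"c": 1000}, seed=2)
        path = tmp_path / "a.sam"
        from refdup.toymap import ReadAlignment

        write_sam([ReadAlignment.unmapped("r", "ACGT")], genome, str(path))
        record = path.read_text().splitlines()[-1].split("\t")
        assert record[1:6] == ["4", "*", "0", "0", "*"]

    def test_record_count_conservation_and_determinism(self, tmp_path):
        genome = make_random_genome({"c": 20_000}, seed=3)
        reads = simulate_reads(genome, 7.5, 150, 0.001, [], seed=4)
        assert len(reads) == round(7.5 * 20_000 / 150)
        idx = index_reference(genome, k=21)
        pairs = [(r.name, r.seq) for r in reads]
        out1, out2 = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(map_reads(pairs, idx), genome, str(out1))
        write_sam(map_reads(pairs, idx), genome, str(out2))
        assert out1.read_bytes() == out2.read_bytes()
        with pysam.AlignmentFile(str(out1), "r") as fh:
            assert sum(1 for _ in fh) == len(reads)


class TestBruteForceAgreement:
    def test_best_hit_and_tie_structure_match_full_scan(self, dup_genome):
        """Mapper best-mismatch and tie=>MAPQ0 agree with exhaustive scan."""
        ref, truth = dup_genome
        idx = index_reference(ref, k=21)
        reads = simulate_reads(ref, 1.0, 150, 0.01, [], seed=21)[:150]
        for r in reads:
            aln = map_read(r.name, r.seq, idx)
            best, hits = brute_force_best_hits(r.seq, ref)
            if not aln.is_mapped:
                assert best > 8  # default ceiling for 150 bp
                continue
            assert aln.mismatches == best
            assert (aln.mapq == 0) == (len(hits) >= 2)
            if aln.mapq > 0:
                assert (aln.contig, aln.pos, aln.strand) == hits[0]

    def test_masking_monotonicity_for_retained_copy_reads(self, dup_genome):
        """Masking the extra copy never lowers MAPQ or moves retained-copy reads."""
        ref, truth = dup_genome
        masked = mask_fasta(
            ref, [MaskInterval(truth.dest_contig, truth.dest_start, truth.dest_end)]
        )
        idx_pre = index_reference(ref, k=21)
        idx_post = index_reference(masked, k=21)
        for start in range(10_000, 11_850, 37):
            read = ref["chrA"][start : start + 150]
            pre = map_read("r", read, idx_pre)
            post = map_read("r", read, idx_post)
            assert post.mapq >= pre.mapq
            assert (post.contig, post.pos) == ("chrA", start)
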