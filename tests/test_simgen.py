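"""Synthetic-truth generation and the end-to-end demonstration pipeline."""

import numpy as np
import pytest

from refdup.alnqc import depth_profiles
from refdup.dupscan import alignment_identity
from refdup.simgen import (
    DemoConfig,
    PlantedVariant,
    demo_pipeline,
    make_random_genome,
    plant_duplicate,
    simulate_reads,
    write_fastq,
)
from refdup.toymap import index_reference, map_reads, write_sam
from refdup.varcall import CallerParams, build_pileup, call_variants
from refdup._util import revcomp


class TestMakeRandomGenome:
    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            make_random_genome({"c": 0}, seed=1)

    def test_fixed_seed_reproduces_genome(self):
        assert make_random_genome({"c": 5000}, 9) == make_random_genome({"c": 5000}, 9)

    def test_base_composition_near_uniform(self):
        genome = make_random_genome({"c": 100_000}, seed=2)
        seq = genome["c"]
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.02)


class TestPlantDuplicate:
    def test_zero_divergence_copy_is_identical(self):
        genome = make_random_genome({"c": 5000}, seed=3)
        ref, truth = plant_duplicate(genome, ("c", 1000, 3000), "d", 0, 0.0, seed=4)
        assert ref["d"] == genome["c"][1000:3000]
        assert truth.substitution_positions == []

    def test_substitution_count_is_binomial(self):
        genome = make_random_genome({"c": 12_000}, seed=5)
        ref, truth = plant_duplicate(genome, ("c", 0, 10_000), "d", 0, 0.01, seed=6)
        n_subs = len(truth.substitution_positions)
        # Binomial(10000, 0.01): mean 100, sd ~9.95; assert within 4 sigma
        assert abs(n_subs - 100) <= 4 * np.sqrt(10_000 * 0.01 * 0.99)
        diffs = sum(a != b for a, b in zip(genome["c"][:10_000], ref["d"]))
        assert diffs == n_subs

    def test_identity_of_copy_matches_divergence(self):
        genome = make_random_genome({"c": 12_000}, seed=7)
        ref, _ = plant_duplicate(genome, ("c", 0, 10_000), "d", 0, 0.01, seed=8)
        identity, _ = alignment_identity(genome["c"][:10_000], ref["d"])
        assert identity == pytest.approx(99.0, abs=0.5)

    def test_insertion_into_existing_contig_shifts_downstream(self):
        genome = make_random_genome({"c": 5000}, seed=9)
        ref, truth = plant_duplicate(genome, ("c", 3000, 4000), "c", 100, 0.0, seed=10)
        assert len(ref["c"]) == 6000
        assert ref["c"][100:1100] == genome["c"][3000:4000]
        # truth tracks the shifted source location
        assert (truth.src_start, truth.src_end) == (4000, 5000)
        assert ref["c"][4000:5000] == genome["c"][3000:4000]


class TestSimulateReads:
    def test_read_count_matches_coverage_identity(self):
        genome = make_random_genome({"c": 10_000}, seed=11)
        reads = simulate_reads(genome, 50, 150, 0.0, [], seed=12)
        assert len(reads) == round(50 * 10_000 / 150)

    def test_error_free_reads_equal_their_source_slice(self):
        genome = make_random_genome({"c": 5000}, seed=13)
        for r in simulate_reads(genome, 2, 100, 0.0, [], seed=14):
            source = genome[r.contig][r.start : r.start + 100]
            assert r.seq == (source if r.strand == "+" else revcomp(source))

    def test_variant_carrier_count_is_binomial_in_vaf(self):
        genome = make_random_genome({"c": 10_000}, seed=15)
        variant = PlantedVariant("c", 5000, genome["c"][5000],
                                 "A" if genome["c"][5000] != "A" else "C", 0.5)
        reads = simulate_reads(genome, 100, 150, 0.0, [variant], seed=16)
        covering = [r for r in reads if r.start <= 5000 < r.start + 150]
        carriers = sum(bool(r.carries_alt) for r in reads)
        n = len(covering)
        assert abs(carriers - 0.5 * n) <= 4 * np.sqrt(n * 0.25)

    def test_ref_base_mismatch_rejected(self):
        genome = make_random_genome({"c": 1000}, seed=17)
        wrong = "A" if genome["c"][500] == "C" else "C"
        bad = PlantedVariant("c", 500, wrong, "G", 0.5)
        with pytest.raises(ValueError, match="ref mismatch"):
            simulate_reads(genome, 1, 100, 0.0, [bad], seed=18)

    def test_fixed_seed_reproduces_fastq_bytes(self, tmp_path):
        genome = make_random_genome({"c": 5000}, seed=19)
        p1, p2 = tmp_path / "a.fq", tmp_path / "b.fq"
        write_fastq(simulate_reads(genome, 5, 100, 0.01, [], seed=20), p1)
        write_fastq(simulate_reads(genome, 5, 100, 0.01, [], seed=20), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSplitCoverage:
    def test_tied_reads_split_between_copies_halve_locus_depth(self, tmp_path):
        """With arbitrary tie assignment each reference copy shows ~half depth.

        The sample carries one copy of the locus; the reference carries two
        identical copies.  Every interior read ties and is assigned to one
        copy at random, so the total depth observed at each reference copy
        is about half the simulated depth.
        """
        depth = 60
        sample = make_random_genome({"c": 30_000}, seed=31)
        reference, truth = plant_duplicate(
            sample, ("c", 10_000, 14_000), "dup", 0, 0.0, seed=32
        )
        reads = simulate_reads(sample, depth, 150, 0.0, [], seed=33)
        idx = index_reference(reference, k=21)
        alns = map_reads(
            [(r.name, r.seq) for r in reads], idx, tie_break="random", seed=34
        )
        sam = tmp_path / "split.sam"
        write_sam(alns, reference, str(sam))
        profiles = depth_profiles(str(sam), reference.lengths)
        interior_c = profiles["c"].total[10_150:13_850]
        interior_dup = profiles["dup"].total[150:3_850]
        assert np.mean(interior_c) == pytest.approx(depth / 2, rel=0.15)
        assert np.mean(interior_dup) == pytest.approx(depth / 2, rel=0.15)
        # splitting conserves reads: the two halves sum to the full depth
        assert np.mean(interior_c) + np.mean(interior_dup) == pytest.approx(
            depth, rel=0.1
        )


class TestDemoPipeline:
    def test_control_without_duplicate_calls_variant_directly(self, tmp_path):
        """No duplicate planted: mapping is clean and the variant is called."""
        genome = make_random_genome({"c": 30_000}, seed=41)
        variant = PlantedVariant(
            "c", 15_000, genome["c"][15_000],
            "A" if genome["c"][15_000] != "A" else "C", 0.5,
        )
        reads = simulate_reads(genome, 80, 150, 0.001, [variant], seed=42)
        idx = index_reference(genome, k=21)
        sam = tmp_path / "ctl.sam"
        write_sam(map_reads([(r.name, r.seq) for r in reads], idx), genome, str(sam))
        profile = depth_profiles(str(sam), genome.lengths)["c"]
        assert profile.depth_mq0.sum() == 0
        calls = call_variants(build_pileup(str(sam), genome, 1), CallerParams())
        assert [(c.pos, c.alt) for c in calls] == [(15_000, variant.alt)]

    def test_demo_report_is_reproducible_and_writes_artifacts(self, tmp_path):
        cfg = DemoConfig(
            genome_len=20_000, dup_start=8_000, dup_len=3_000,
            variant_offset=1_500, mean_depth=60.0, seed=7,
        )
        r1 = demo_pipeline(cfg, out_dir=str(tmp_path / "run1"))
        r2 = demo_pipeline(cfg)
        assert r1 == r2
        for name in ("reference.fa", "reference.masked.fa", "reads.fq",
                     "pre_mask.sam", "post_mask.sam", "truth.json"):
            assert (tmp_path / "run1" / name).exists()
        assert r1.dup_found
        assert r1.pre_interior_median_mq_pass == 0.0
        assert not r1.variant_called_pre
        assert r1.variant_called_post
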