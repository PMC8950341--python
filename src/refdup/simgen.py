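"""Synthetic genomes, planted duplications, planted SNVs and simulated reads.

The generator reproduces, at desk scale, the study conditions of the
reference-duplication failure mode: a sample genome with a single copy of a
locus, a *reference* genome carrying an extra near-identical copy of that
locus (the assembly artifact), uniform-coverage reads drawn from the sample
with a heterozygous-like SNV planted at a hotspot position, and the full
diagnose-and-fix loop (map, QC, call; scan, mask, re-map, re-call).

Scale of the default scenario: a 100 kb genome with a 10 kb duplicated
block mirrors the real event (a ~150 kb block at 99.0% identity) at a size
that runs in seconds; divergence 0.01 between the copies corresponds to
99.0% alignment identity, and divergence 0 is the worst case in which every
interior read ties exactly between the two copies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .reference_io import Genome, MaskInterval, mask_fasta, write_fasta
from .dupscan import scan_duplications
from .toymap import index_reference, map_reads, write_sam
from .alnqc import depth_profiles, lower_median
from .varcall import CallerParams, build_pileup, call_variants
from ._util import revcomp

__all__ = [
    "SimTruth",
    "PlantedVariant",
    "SimulatedRead",
    "make_random_genome",
    "plant_duplicate",
    "simulate_reads",
    "write_fastq",
    "DemoConfig",
    "DemoReport",
    "demo_pipeline",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedVariant:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    vaf: float


@dataclass
class SimTruth:
    """Ground truth of a planted duplication: regions, divergence, seed."""

    src_contig: str
    src_start: int
    src_end: int
    dest_contig: str
    dest_start: int
    dest_end: int
    divergence: float
    substitution_positions: list[int]  # offsets within the copy
    seed: int


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    seq: str
    contig: str
    start: int  # true 0-based start on the source genome
    strand: str
    carries_alt: tuple[int, ...]  # positions of planted variants on the read


def make_random_genome(contig_lengths: dict[str, int], seed: int) -> Genome:
    """I.i.d. uniform A/C/G/T sequence per contig; reproducible for a seed."""
    rng = np.random.default_rng(seed)
    contigs = {}
    for name, length in contig_lengths.items():
        if length < 1:
            raise ValueError(f"contig {name!r} length must be positive")
        contigs[name] = rng.choice(_ALPHABET, size=length).tobytes().decode("ascii")
    return Genome(contigs)


def plant_duplicate(
    genome: Genome,
    src: tuple[str, int, int],
    dest_contig: str,
    dest_pos: int,
    divergence: float,
    seed: int,
) -> tuple[Genome, SimTruth]:
    """Insert a diverged copy of ``src`` into the genome.

    If ``dest_contig`` already exists the copy is inserted at ``dest_pos``
    (downstream sequence shifts right); otherwise a new contig is appended
    holding just the copy — the default demo layout, emulating added
    assembly content distal to the original locus.  The copy differs from
    the source by independent per-base substitutions at rate ``divergence``
    (alternatives drawn uniformly); realized substitution offsets are
    recorded in the returned :class:`SimTruth`.
    """
    contig, start, end = src
    if not 0 <= start < end <= len(genome[contig]):
        raise ValueError(f"source region [{start}, {end}) out of bounds")
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    copy = bytearray(genome[contig][start:end], "ascii")
    sub_positions = np.flatnonzero(rng.random(len(copy)) < divergence)
    for off in sub_positions:
        alternatives = [b for b in b"ACGT" if b != copy[off]]
        copy[off] = alternatives[int(rng.integers(3))]
    copy_seq = copy.decode("ascii")

    contigs = dict(genome.items())
    if dest_contig in contigs:
        if dest_contig == contig and start < dest_pos < end:
            raise ValueError("destination position lies inside the source region")
        old = contigs[dest_contig]
        if not 0 <= dest_pos <= len(old):
            raise ValueError(f"dest_pos {dest_pos} out of bounds")
        contigs[dest_contig] = old[:dest_pos] + copy_seq + old[dest_pos:]
        dest_start = dest_pos
        if dest_contig == contig and dest_pos <= start:
            # insertion upstream of the source shifts it right
            start += len(copy_seq)
            end += len(copy_seq)
    else:
        contigs[dest_contig] = copy_seq
        dest_start = 0
    truth = SimTruth(
        contig, start, end,
        dest_contig, dest_start, dest_start + len(copy_seq),
        divergence, [int(p) for p in sub_positions], seed,
    )
    return Genome(contigs), truth


def simulate_reads(
    genome: Genome,
    mean_depth: float,
    read_len: int,
    error_rate: float,
    variants: Sequence[PlantedVariant],
    seed: int,
) -> list[SimulatedRead]:
    """Uniform-coverage single-end reads with planted SNVs.

    Read count = round(mean_depth x genome length / read_len); start
    positions are uniform over all valid placements, strands Bernoulli(1/2).
    A read covering a planted variant carries the alt allele with
    probability equal to the variant's VAF.  Sequencing errors are i.i.d.
    substitutions at ``error_rate`` per base.
    """
    lengths = genome.lengths
    if read_len > min(lengths.values()):
        raise ValueError("read_len exceeds the shortest contig")
    rng = np.random.default_rng(seed)
    names = list(genome)
    valid = np.array([lengths[c] - read_len + 1 for c in names], dtype=np.int64)
    total = int(round(mean_depth * genome.total_length() / read_len))
    contig_idx = rng.choice(len(names), size=total, p=valid / valid.sum())
    starts = rng.integers(0, valid[contig_idx])
    strands = rng.random(total) < 0.5

    by_contig: dict[str, list[PlantedVariant]] = {}
    for v in variants:
        if genome[v.contig][v.pos] != v.ref:
            raise ValueError(
                f"variant ref mismatch at {v.contig}:{v.pos}: "
                f"genome has {genome[v.contig][v.pos]}, variant says {v.ref}"
            )
        by_contig.setdefault(v.contig, []).append(v)

    reads: list[SimulatedRead] = []
    for i in range(total):
        contig = names[int(contig_idx[i])]
        start = int(starts[i])
        seq = bytearray(genome[contig][start : start + read_len], "ascii")
        carried = []
        for v in by_contig.get(contig, ()):
            if start <= v.pos < start + read_len and rng.random() < v.vaf:
                seq[v.pos - start] = ord(v.alt)
                carried.append(v.pos)
        if error_rate > 0:
            for off in np.flatnonzero(rng.random(read_len) < error_rate):
                alternatives = [b for b in b"ACGT" if b != seq[off]]
                seq[off] = alternatives[int(rng.integers(3))]
        out = seq.decode("ascii")
        strand = "-" if strands[i] else "+"
        if strand == "-":
            out = revcomp(out)
        reads.append(
            SimulatedRead(f"read_{i:07d}", out, contig, start, strand, tuple(carried))
        )
    return reads


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth_json(truth: SimTruth, variants: Sequence[PlantedVariant], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"duplication": asdict(truth), "variants": [asdict(v) for v in variants]},
            fh,
            indent=2,
        )


@dataclass
class DemoConfig:
    """Scenario parameters for the end-to-end demonstration."""

    genome_len: int = 100_000
    contig: str = "chr_main"
    dup_contig: str = "chr_dup"
    dup_start: int = 45_000
    dup_len: int = 10_000
    divergence: float = 0.0
    read_len: int = 150
    mean_depth: float = 100.0
    error_rate: float = 0.001
    variant_offset: int = 5_000  # variant position within the duplicated locus
    variant_vaf: float = 0.5
    k: int = 21
    caller: CallerParams = field(default_factory=CallerParams)
    seed: int = 42

    @property
    def dup_end(self) -> int:
        return self.dup_start + self.dup_len

    @property
    def variant_pos(self) -> int:
        return self.dup_start + self.variant_offset


@dataclass
class DemoReport:
    """Pre/post-masking diagnostics over the duplicated locus."""

    config_seed: int
    divergence: float
    dup_found: bool
    dup_identity_pct: float | None
    dup_region_b: tuple[str, int, int] | None
    pre_locus_median_mq_pass: float
    post_locus_median_mq_pass: float
    pre_interior_median_mq_pass: float
    post_interior_median_mq_pass: float
    pre_locus_mq0_fraction: float
    post_locus_mq0_fraction: float
    genome_median_mq_pass_post: float
    genome_median_mq_pass_pre: float
    variant_called_pre: bool
    variant_called_post: bool
    variant_vaf_post: float | None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_tsv(self, path) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            fh.write("\t".join(d) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")


def _locus_stats(profile, start: int, end: int, read_len: int):
    locus_pass = profile.depth_mq_pass[start:end]
    locus_total = profile.total[start:end]
    interior = slice(start + read_len, end - read_len)
    mq0 = profile.depth_mq0[start:end].sum()
    total = locus_total.sum()
    return (
        lower_median(locus_pass),
        lower_median(profile.depth_mq_pass[interior]),
        (mq0 / total) if total else 0.0,
    )


def demo_pipeline(config: DemoConfig, out_dir=None) -> DemoReport:
    """Run the full diagnose-and-fix loop on one synthetic scenario.

    Sample genome (one copy of the locus) -> reference with a planted
    duplicate copy -> reads from the sample -> map to the flawed reference
    -> depth QC + variant calling; then: scan the reference for the
    duplication -> hard-mask the extra copy -> re-map -> re-QC -> re-call.
    When ``out_dir`` is given, FASTA/FASTQ/SAM/JSON artifacts are written
    there; otherwise everything stays in memory except two temporary SAMs.
    """
    import os
    import tempfile

    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    seed_genome, seed_dup, seed_reads = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    sample = make_random_genome({cfg.contig: cfg.genome_len}, seed_genome)
    reference, truth = plant_duplicate(
        sample,
        (cfg.contig, cfg.dup_start, cfg.dup_end),
        cfg.dup_contig,
        0,
        cfg.divergence,
        seed_dup,
    )
    variant = PlantedVariant(
        cfg.contig,
        cfg.variant_pos,
        sample[cfg.contig][cfg.variant_pos],
        _alt_base(sample[cfg.contig][cfg.variant_pos]),
        cfg.variant_vaf,
    )
    reads = simulate_reads(
        sample, cfg.mean_depth, cfg.read_len, cfg.error_rate, [variant], seed_reads
    )

    tmp = None
    if out_dir is None:
        tmp = tempfile.TemporaryDirectory()
        out_dir = tmp.name
    else:
        os.makedirs(out_dir, exist_ok=True)

    try:
        write_fasta(reference, os.path.join(out_dir, "reference.fa"))
        write_fastq(reads, os.path.join(out_dir, "reads.fq"))
        write_truth_json(truth, [variant], os.path.join(out_dir, "truth.json"))

        read_pairs = [(r.name, r.seq) for r in reads]
        sam_pre = os.path.join(out_dir, "pre_mask.sam")
        index_pre = index_reference(reference, cfg.k)
        write_sam(map_reads(read_pairs, index_pre), reference, sam_pre)

        profiles_pre = depth_profiles(sam_pre, reference.lengths)
        pileup_pre = build_pileup(sam_pre, reference, cfg.caller.min_mapq)
        calls_pre = call_variants(pileup_pre, cfg.caller)

        pairs = scan_duplications(reference, k=cfg.k)
        dup_found = len(pairs) > 0
        if dup_found:
            top = pairs[0]
            mask = [MaskInterval(top.contig_b, top.start_b, top.end_b)]
            masked = mask_fasta(reference, mask)
            dup_identity = top.identity_pct
            dup_region_b = (top.contig_b, top.start_b, top.end_b)
        else:
            masked = reference
            dup_identity = None
            dup_region_b = None

        sam_post = os.path.join(out_dir, "post_mask.sam")
        write_fasta(masked, os.path.join(out_dir, "reference.masked.fa"))
        index_post = index_reference(masked, cfg.k)
        write_sam(map_reads(read_pairs, index_post), masked, sam_post)

        profiles_post = depth_profiles(sam_post, masked.lengths)
        pileup_post = build_pileup(sam_post, masked, cfg.caller.min_mapq)
        calls_post = call_variants(pileup_post, cfg.caller)

        pre = profiles_pre[cfg.contig]
        post = profiles_post[cfg.contig]
        pre_locus, pre_interior, pre_mq0 = _locus_stats(
            pre, cfg.dup_start, cfg.dup_end, cfg.read_len
        )
        post_locus, post_interior, post_mq0 = _locus_stats(
            post, cfg.dup_start, cfg.dup_end, cfg.read_len
        )

        def genome_median(profile):
            outside = np.concatenate(
                [
                    profile.depth_mq_pass[: cfg.dup_start],
                    profile.depth_mq_pass[cfg.dup_end :],
                ]
            )
            return lower_median(outside)

        hit_pre = _find_call(calls_pre, variant)
        hit_post = _find_call(calls_post, variant)
        return DemoReport(
            config_seed=cfg.seed,
            divergence=cfg.divergence,
            dup_found=dup_found,
            dup_identity_pct=dup_identity,
            dup_region_b=dup_region_b,
            pre_locus_median_mq_pass=pre_locus,
            post_locus_median_mq_pass=post_locus,
            pre_interior_median_mq_pass=pre_interior,
            post_interior_median_mq_pass=post_interior,
            pre_locus_mq0_fraction=pre_mq0,
            post_locus_mq0_fraction=post_mq0,
            genome_median_mq_pass_post=genome_median(post),
            genome_median_mq_pass_pre=genome_median(pre),
            variant_called_pre=hit_pre is not None,
            variant_called_post=hit_post is not None,
            variant_vaf_post=hit_post.vaf if hit_post else None,
        )
    finally:
        if tmp is not None:
            tmp.cleanup()


def _alt_base(ref: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}[ref]


def _find_call(calls, variant: PlantedVariant):
    for c in calls:
        if c.contig == variant.contig and c.pos == variant.pos and c.alt == variant.alt:
            return c
    return None
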