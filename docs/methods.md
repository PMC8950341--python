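# Methods

## The failure mode being modeled

A reference assembly that carries two near-identical copies of a locus
breaks short-read analysis in two coupled steps. First, the aligner cannot
distinguish the copies: any read wholly contained in the duplicated block is
equally consistent with both, and aligners mark such reads with mapping
quality 0 (choosing one placement arbitrarily). Second, variant callers
exclude MAPQ-0 reads, so the effective (MQ>0) depth over the block drops
toward zero and variants fail the caller's depth/alt-count thresholds. The
remedy is hard masking: replacing one copy with `N` keeps the coordinate
system intact but removes all seeds from the masked copy, restoring unique
placement — and variant detection — at the retained locus.

`refdup` implements each stage explicitly so the mechanism can be produced,
measured and repaired under controlled conditions.

## Duplication scanning

Self-comparison proceeds in four steps.

1. **k-mer index** (default k = 21, forward strand only). k-mers containing
   `N` are never indexed — the same property that makes masking effective.
2. **Anchors**: every ordered pair of distinct positions sharing a k-mer,
   skipping k-mers occurring more than `max_kmer_occurrences` (50) times to
   suppress low-complexity repeats.
3. **Chaining**: anchors grouped by contig pair and sorted by
   (diagonal = posB − posA, posA); a cluster absorbs the next anchor when
   its diagonal is within `max_diagonal_drift` (100 bp) of the cluster's
   first anchor and the positional gap is at most `max_gap` (1000 bp).
   Clusters with fewer than `min_anchors` (5) anchors are dropped. Ties in
   merge order are resolved by the (diagonal, posA) sort — deterministic.
4. **Boundary refinement**: a substitution near a region edge breaks the
   terminal k-mers, so anchor bounds can stop short of the true boundary.
   Each candidate is therefore extended outward by ungapped X-drop
   extension (match +1, mismatch −2, drop threshold 20): inside the
   homologous block the score climbs at ~0.97/bp at 1% divergence, while in
   random flanking sequence it falls at ~1.25/bp, so the score maximum
   localizes the boundary to within a few bases. On planted 5 kb duplicates
   this recovers boundaries within ±1 bp in practice, far inside the ±k
   acceptance band.

**Percent identity** is 100 × matches / alignment columns of a *global*
pairwise alignment; gap columns count against identity. This definition has
to be fixed explicitly because "percent identity" is not standardized; the
column-denominator convention is the common one, and a block copied at
per-base substitution divergence d measures ≈ 100(1 − d) under it. Two
scoring routes share this definition: below 4 kb combined length, the exact
dynamic program (match +1, mismatch −1, gap −2, Biopython `PairwiseAligner`);
above it, the edit-distance alignment path (edlib, effectively banded),
which is exact for the unit-cost objective and orders of magnitude faster on
the 10–150 kb regions the scanner targets. The two routes agree to well
within 0.05 percentage points on substitution-diverged pairs (tested); their
optimal paths can differ by an occasional gap placement, which moves the
column count by a base or two and the identity by far less than the
reported precision.

Forward-strand duplications only; inverted (reverse-complement) duplicates
are out of scope. Reported pairs never overlap themselves, and each pair is
reported once with `region_a` the positionally earlier copy — the other copy
is the natural mask target and is exported as BED.

## MAPQ-stratified depth and collapse regions

Depth counts reference-consuming CIGAR operations (M, =, X **and D**): a
deleted reference base is still spanned by the read, and counting it keeps
depth continuous across small indels. Whether published coverage figures
count deletions is generally unstated; we fix and document this choice.
Secondary, supplementary and duplicate-marked records are excluded. The
pass stratum is MAPQ ≥ `min_mapq` with default 1, i.e. the "MQ > 0"
statistic; the threshold is configurable.

Collapse regions: sliding windows (default 500 bp, step half a window) are
eligible when summed depth ≥ `min_total_depth` (10 — avoids calling
"collapse" in unsequenced gaps); windows whose MQ0 share of total depth is
at least `min_mq0_fraction` (0.5) are merged, and merged regions shorter
than `min_len` (1000 bp) are dropped. Feature summaries use the *lower
middle* value as the median of an even-length sample: depths are integers
and this keeps the statistic exact and platform-independent.

## The toy mapper

Seeds are non-overlapping k-mers at stride k (k = 21) over the read and its
reverse complement; each seed hit proposes a full-length ungapped candidate
placement, scored by Hamming mismatches. The best candidate wins when its
mismatch count is within `max_mismatches` (⌈0.05 × read length⌉, i.e. 8 for
150 bp — guaranteeing seed survival at 1% divergence). MAPQ is a coarse
ladder: 0 on a tie for best; otherwise min(60, 20 × (second_best − best)),
with a lone candidate treated as uncontested (60). Ties are broken by
smallest (contig order, position) by default — deterministic, byte-identical
SAM across runs — or assigned uniformly at random with a seeded RNG
(`tie_break="random"`), which emulates the arbitrary primary selection of
production aligners and reproduces the halved-coverage signature when one
sample locus splits across two reference copies. Ungapped alignment is
sufficient to reproduce the MAPQ-collapse phenomenon and keeps the
brute-force full-scan oracle trivial; gapped alignment, paired ends and base
qualities are deliberately out of scope.

## The variant caller

Pure threshold logic in the VarScan single-sample style: per pileup column
the alt allele is the most frequent non-reference base (alphabetical
tie-break), and a call requires depth ≥ 20, alt reads ≥ 5, VAF ≥ 0.05, and —
with the strand filter on — at least one alt read per strand with no strand
carrying more than 90% of alt support. The 90% interpretation of the strand
filter is a documented choice (the flag's exact semantics are not published
as an equation) and is configurable. No per-variant significance test is
applied, a deliberate simplification: the phenomenon under study is driven
entirely by the MAPQ gate (`min_mapq` = 1), which removes MAPQ-0 reads from
the pileup before any threshold is evaluated. Base qualities are ignored;
the simulator's quality strings are uninformative by design.

## The synthetic scenarios

The generator models the study conditions directly:

- **Sample vs reference**: the *sample* genome carries one copy of the
  locus; the *reference* carries an extra copy planted at divergence d (the
  assembly artifact). Reads are simulated from the sample and mapped to the
  reference — exactly the situation in which real data meet a duplicated
  assembly. The copy goes on its own contig by default, keeping all sample
  coordinates stable.
- **Default demo scenario**: 100 kb genome, 10 kb duplicated block,
  divergence ∈ {0, 0.01}, 150 bp reads at 100× mean depth, sequencing error
  0.001/bp (typical short-read substitution error), one planted SNV at the
  locus center with VAF 0.5 (a heterozygous-like hotspot), seed 42. The
  10 kb / 100 kb sizes are a ~15× linear scale-down of the real ~150 kb
  event, chosen so the full loop runs in seconds while leaving the locus
  much larger than read length and window sizes; divergence 0.01 mirrors
  the 99.0%-identity case and divergence 0 is the deterministic worst case.
- **Variants are injected at read level**, not into the genome, so the
  reference remains the caller's truth — the somatic-variant situation.
- Read starts are uniform over valid placements, strands Bernoulli(1/2),
  alt-allele carriage Bernoulli(VAF) per covering read, substitution errors
  i.i.d. All stages derive their RNG streams from one seed; fixed seed gives
  byte-identical FASTA/FASTQ/SAM/VCF/report outputs.

What the simulation does *not* model: capture bias of targeted panels,
paired-end structure, indel divergence between copies, base-quality error
profiles, PCR duplicates. Passing tests therefore demonstrate the
multimapping mechanism and its repair, not end-to-end accuracy on real
panel data — on real data the same diagnosis is run with a production
aligner upstream.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; 1-based inclusive only in
  printed region strings and VCF POS.
- Masking unions overlapping intervals silently and is idempotent; length
  zero intervals are rejected at BED parse time with a line number.
- Ambiguity codes (R, Y, …) are normalized to `N` on FASTA load; genuinely
  non-nucleotide characters are an error naming the offending position.
- Empty pileups, zero-depth contigs and duplicate-free genomes return empty
  results rather than errors throughout.
- `lower_median` of an empty feature is an error (features must be
  non-empty intervals by BED validation).

## Problem sizes used by the test suite and acceptance script

Unit tests run on 1–30 kb genomes; the mechanism tests run the 100 kb demo
over ten seeds; detector recovery uses 50 kb genomes with planted 5 kb
duplicates over ten seeds; brute-force oracle comparisons use a 20 kb + 2 kb
reference with 1000 reads. These sizes were chosen so the scaling arguments
above hold (locus ≫ read length ≫ k) while the whole suite completes in a
few minutes on a single core.
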