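# Methods

`tetrack` tracks individual transposable-element (TE) copies between two
genome assemblies of closely related strains and tests whether genomic
variants are enriched in particular annotations within restricted
chromosomal territories.  This note describes the models and procedures,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## TE tracking by SNP fingerprints

TE families are highly repetitive: two copies of the same family are often
sequence-identical, so an individual copy cannot, in general, be followed
from one assembly to another.  The tracking procedure exploits strain
divergence to break this symmetry:

1. **Fingerprinting.** Reference TE annotations are intersected with the
   homozygous SNPs called between the two strains.  A copy overlapped by at
   least one SNP acquires a *fingerprint*: the set of (offset, ref base,
   alt base) substitutions falling inside it.
2. **Projection.** The variant bases are applied to the reference copy's
   sequence, producing the sequence that the same element should have in
   the query assembly.
3. **Uniqueness.** A copy is retained only if its projected sequence occurs
   exactly once among all projected sequences *and* its raw sequence occurs
   exactly once among all reference TE sequences.  Both checks consider
   both orientations (a copy and its reverse complement are the same
   element).  The stricter both-sets rule is used because a duplicate on
   either side makes the pairing ambiguous.
4. **Cross-reference.** Each projected sequence is looked up among the
   query assembly's annotated TE sequences by exact, full-length string
   equality (again in either orientation, with an `orientation_flip` flag
   on matches).  Exactly one hit is a `unique` match; two or more hits mean
   the element is duplicated in the query and the copy is reported as
   `ambiguous_duplication` — the data cannot say which locus is the
   original; no hit means the element is not detectable.

Indel variants are excluded from fingerprints: an indel changes the copy's
length and breaks exact comparison.  TEs overlapped by an indel are dropped
from tracking with a logged count.  Heterozygous calls are excluded by
default because a segregating allele would make the projected sequence
unstable across the pooled population.

## Synteny map and the alignment-expected coordinate

Whether a matched copy *moved* is decided by comparing its observed query
start coordinate with the coordinate predicted by whole-genome alignment.

The internal aligner is MUM-style: anchors are canonical k-mers (default
k = 21, odd so a canonical k-mer is never its own reverse complement) that
occur exactly once in each genome counting both strands.  Anchors are
sorted by reference position and cut into runs wherever the (query
chromosome, orientation, diagonal) triple changes or the gap to the next
anchor exceeds `max_gap` (default 10 kb); runs of at least 5 anchors become
collinear blocks.  Because every block has a constant diagonal, the
base-level lift inside a block is an exact offset (forward) or reflection
(reverse).

Cutting on the globally sorted anchor sequence — rather than chaining each
diagonal separately — is deliberate: cumulative offsets can *cancel* (a
deletion followed by an equal-sized insertion returns to an earlier
diagonal), and a per-diagonal chain would then bridge across foreign
territory and lift positions in the middle with the wrong offset.  An
anchor of a different diagonal always interrupts a globally sorted run, so
such bridges cannot form.

Two further rules deal with repeats:

- **Repeat masking at block level.** A relocated TE's own unique k-mers
  would form a short block connecting its reference source to its query
  destination, and the lift would follow the moved element instead of the
  collinear backbone.  Blocks whose reference span falls entirely within
  one annotated repeat interval (expanded by k) are therefore discarded
  when a repeat annotation is supplied; the `track` pipeline always passes
  the reference TE annotation.  Anchors *inside* unmoved repeats are kept —
  they extend the surrounding block through the repeat.
- **Overlap resolution.** Junction-crossing pseudo-anchors can extend a
  block a few bases past a true breakpoint; overlapping blocks are
  reconciled by letting the longer block win and trimming the shorter one
  back (coordinates stay exact because blocks are constant-diagonal).

`lift(chrom, pos)` returns the expected query coordinate.  Between (or
beyond) blocks the *preceding* block's frame is extended forward and the
result flagged `interpolated`.  The preceding frame is the right choice for
this detector: an excision at the queried position shifts the frame of
everything downstream but leaves the upstream frame intact, so
extrapolating forward is exact for the start coordinate of a potentially
excised element, whereas the nearest-edge rule misclassifies unmoved
elements that happen to sit next to a movement site.

A PAF file from an external whole-genome aligner can be imported instead
(`blocks_from_paf`); rows shorter than `min_len` (default 1 kb) are dropped
and reference overlaps are resolved by keeping the longer row.  Both paths
produce the same `SyntenyMap` type.

## Movement classification

For each uniquely matched copy, with `tolerance` defaulting to 100 bp:

1. Lift the reference start.  An unliftable position (chromosome absent
   from the map) gives verdict `unplaced`.
2. Same query chromosome and |observed − expected| ≤ tolerance →
   `unmoved`.  Different chromosome → interchromosomal candidate; same
   chromosome but a larger discrepancy → intrachromosomal candidate with
   distance |observed − expected| (query frame).
3. **Nested exclusion.** A candidate fully contained in a different TE of
   the same family (in either genome's annotation) is `excluded_nested`:
   local movement within the enveloping element cannot be established.
4. **Flank filter.** The 50 bp immediately upstream and downstream of the
   copy at its old (reference) and new (query) locus are aligned —
   upstream vs upstream, downstream vs downstream — by affine-gap
   Smith–Waterman.  If either flank pair reaches ≥ 90 % identity the
   candidate is `excluded_flank`: near-identical flanks at both loci are
   the signature of an alignment/assembly artifact rather than a genuine
   relocation.  Survivors keep the verdict `intra` or `inter`.

The 100 bp tolerance absorbs residual frame drift from unanchored bases
near block edges.  The flank filter is applied to both candidate classes by
default for symmetry (`flank_filter_inter=False` restricts it to the
intrachromosomal list); the per-flank "either" rule is the default, with
`both` and `concat` (one alignment of the concatenated 100 bp) available.

### Alignment scoring

Match +1, mismatch −19, and a gap of length L costs 39 + 3·L — the scoring
of the minimap2 `asm5` preset for genome pairs of low divergence, collapsed
to a single affine component (at 50 bp scale the preset's long-gap regime
is unreachable).  Flank identity is defined as identical aligned columns of
the optimal local alignment divided by the *longer input length*, not the
alignment span, so a short spurious local hit between unrelated flanks
scores low; an empty optimal alignment has score 0 and identity 0.  Among
co-optimal alignments the traceback prefers diagonal over vertical over
horizontal moves; the score is unaffected by this tie-break and only the
identity of degenerate co-optima can differ.  The implementation is the
standard three-matrix dynamic program, O(nm) time; it is intended for flank
( ≤ a few hundred bp) comparisons, not whole chromosomes.

## Workspace permutation enrichment

The enrichment engine asks whether a set of variant intervals overlaps an
annotation more (or less) than chance within a *workspace* — a restricted
genomic territory such as the arm-like terminal thirds of a chromosome or
its central domain.  Arms and center are mutually exclusive by
construction: with arm fraction f (default 1/3), arms are [0, f·L) ∪
[(1−f)·L, L) and the center is the remainder, with boundaries rounded
half-down so arm bp + center bp = L exactly.  A labelled BED can override
the fraction rule, e.g. to supply empirically defined domains.

The statistic is nucleotide overlap between the interval unions (shared
bases counted once).  The null distribution re-places every variant
interval independently and uniformly among all start positions that keep
it inside a single workspace segment (lengths preserved; sampled intervals
may overlap each other — forbidding overlap would bias the null for dense
variant sets).  Defaults: 20 000 iterations.  Reported per test:

- observed overlap, null mean and SD;
- log2 fold = log2((observed+1)/(null mean+1)); the 1 bp pseudocount keeps
  the fold finite when overlaps are zero;
- empirical p-values: enrichment tail (1 + #{null ≥ obs})/(n_iter + 1),
  the mirrored depletion tail, and the two-sided value
  min(1, 2·min(enrich, deplete)).  The empirical p is the primary
  statistic;
- a one-sided hypergeometric tail that treats bases as exchangeable draws:
  the probability of drawing at least the observed number of annotated
  bases when variant-bp bases are drawn without replacement from the
  workspace.  This is a deliberate, documented approximation (bases are
  not independent draws) reported alongside the empirical p.

The empirical p-value is valid (sub-uniform under the null) for any
configuration, but its two-sided version is conservative and lumpy when
the overlap statistic takes few distinct values; calibration checks
therefore use configurations with many variant intervals of varied
lengths, where the statistic is near-continuous.  No multiple-testing
correction is applied; cell-level α is the caller's choice.

## The synthetic genome pair

The generator produces a reference/query assembly pair whose statistical
structure mirrors a diverged nematode strain comparison, plus complete
machine-readable truth.  Defaults (the study conditions for the acceptance
checks):

| parameter | default | note |
|---|---|---|
| chromosomes | 3 × 500 kb | grows to ~590 kb after TE insertion |
| TE families | 10 (8 class II, 2 class I) | ~225 copies, ~15 % of the genome; Zator and the other DNA-transposon families dominate |
| per-copy divergence | 0.02 | substitutions vs the family consensus, so copies are distinguishable |
| arm / center SNP rate | 3.5e-3 / 7.5e-4 per bp | genome mean ~2.6e-3; arm density fold ≈ 1.36 (log2 ≈ 0.44) |
| indel rate (arms) | 6e-5 per bp | center scaled by the SNP-rate ratio; ~65 indels per genome, sizes 1–10 bp |
| TE placement weight arm:center | 3:1 | per-bp placement probability |
| planted movements | 5 intra + 5 inter | intra distances sampled from 1–200 kb |
| distractors | 3 nested + 3 identical-flank + 3 duplication | |

Arm domains are the terminal thirds of each chromosome throughout.  The
SNP rates were chosen so that the arm *density fold* matches the published
range for arm enrichment of strain SNPs; the indel density is kept an
order of magnitude below a real strain pair so that collinear blocks stay
long relative to TE size at this miniature genome scale.

Movements are clean cut-and-paste (no excision scar, no target-site
duplication): the detector reasons about annotated intervals and start
coordinates, not excision footprints; TSD modelling would add realism the
detector never sees.  Every moved or distractor TE is guaranteed ≥ 1
internal SNP (forced if background SNPs missed it) because only SNP-bearing
copies are trackable.  Background indels never fall inside TE intervals by
default (`allow_te_indels` enables them to stress-test matching — such TEs
are then dropped by the indel rule).

The distractor classes each exercise one exclusion rule:

- **nested**: a same-family fragment is planted inside an existing copy in
  the reference, and the inner copy is relocated in the query.  It is a
  genuine movement candidate that the nested-exclusion rule must catch (a
  merely nested, unmoved copy would never reach the exclusion step).
- **identical-flank**: a copy is excised and re-inserted at a locus where
  the generator also plants copies of its original 50 bp flanks, emulating
  the repeat-context artifacts that motivate the flank filter.  Expected
  verdict: `excluded_flank`.
- **duplication**: a copy is left in place and an identical second copy
  (same fingerprint) inserted elsewhere on the same chromosome.  Expected
  verdict: `ambiguous_duplication`.

The emitted VCF contains every background SNP/indel and every fingerprint
SNP, all homozygous and all passing the retention filter (QUAL ≥ 30,
alt reads ≥ 10, total reads ≥ 30; QUAL and depths are drawn uniformly above
the thresholds).  Fingerprint SNPs of moved TEs are recorded at their
*reference* coordinates — exactly where a read-based caller would place
them.  Applying the VCF plus the planted movement operations to the
reference reconstructs the query byte-for-byte (a test asserts this with an
independent string editor).

What the generator does **not** emulate, and hence what passing tests do
not show about real data: TE structural features (terminal inverted
repeats, ORFs, target-site preferences), sequencing/assembly error,
heterozygosity and population structure, segmental duplications or
inversions beyond TE movement, GC/isochore structure, and realistic
per-family mobility rates (movement counts are free parameters).  Recovery
of 100 % of planted movements on this generator demonstrates the
correctness of the bookkeeping and decision rules under clean conditions,
not the sensitivity of the method on real assemblies.

## Determinism and degenerate inputs

All randomness flows from `numpy.random.default_rng` seeded from a single
integer; the simulator derives labelled sub-streams (`[seed, 0]` for the
reference, `[seed, 1]` for the query), so identical parameters and seed
give byte-identical FASTA/VCF/TSV outputs.  Degenerate inputs are values,
not errors, wherever a value makes sense: a genome with no unique k-mers
yields an empty synteny map (warning) and every lift is `unplaced`; a TE at
a chromosome end gets truncated flanks (flagged, identity computed on what
exists); an interval longer than every workspace segment is placed at a
maximal segment with a warning.  Hard errors are reserved for genuine
inconsistencies: a SNP whose REF base disagrees with the assembly, overlap
of alt/total read counts, malformed intervals.

## Problem sizes used in the checks

The test suite and the acceptance script run the full pipeline at the
default 3 × 500 kb scale (seconds per run) and use a 3 × 60 kb miniature
for unit-level fixtures; enrichment calibration uses 500 replicates of
1 000-iteration tests and the power check 100 replicates.  These sizes were
chosen so the complete suite runs in well under an hour on one CPU while
every planted-truth comparison still involves hundreds of TE copies and
thousands of variants.
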