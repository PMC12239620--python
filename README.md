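# tetrack

Track individual transposable-element (TE) copies between two genome
assemblies via their SNP fingerprints, and test the enrichment of genomic
variants in annotations within chromosomal arm/center workspaces.

## The problem

When two lineages of the same species diverge — say a pair of *C. elegans*
laboratory isolates separated for thousands of generations — individual
transposons occasionally excise and reinsert elsewhere.  Detecting such
events from two assemblies is hard because TE families are repetitive:
most copies of a family are sequence-identical, so a copy seen at a new
locus cannot normally be told apart from its siblings.

`tetrack` implements a fingerprint-based detector for users comparing
high-quality assemblies of closely related strains:

1. TE copies in the reference assembly that overlap homozygous SNPs
   (QUAL ≥ 30, ≥ 10 variant reads, ≥ 30 total reads) acquire a unique
   sequence fingerprint.
2. The variant bases are applied to each copy, and the projected sequences
   are cross-referenced against the query assembly's TE annotation by
   exact full-length equality (either orientation).
3. A whole-genome synteny map (internal unique-k-mer anchor aligner, or an
   imported PAF) predicts where each matched copy *should* sit in the
   query.  A copy found > 100 bp (configurable) from its alignment-expected
   start is a movement candidate: same chromosome → intrachromosomal,
   different chromosome → interchromosomal.
4. Candidates are screened: copies nested in a same-family TE are excluded,
   as are candidates whose 50 bp flanks at the old and new locus align at
   ≥ 90 % identity under asm5-style Smith–Waterman scoring (+1/−19, gap
   39 + 3·L) — near-identical flanks indicate an alignment artifact, not a
   movement.  A projected sequence found at two query loci is reported as
   an ambiguous duplication.

A companion permutation engine (in the style of the genomic association
tester, GAT) measures the enrichment of variant interval sets in
annotations inside mutually exclusive workspaces — the arm-like terminal
thirds of each chromosome versus its central domain — with uniform
re-placement nulls (20 000 iterations by default), log2 fold enrichment,
empirical p-values and a hypergeometric tail.

Because real strain-pair data ships as multi-gigabyte assemblies, the
package includes a first-class synthetic-genome module that generates a
miniature reference/query pair with planted TE families, arm-biased
variants, known movements and three classes of decoys (nested TEs,
identical-flank relocations, duplications), plus machine-readable truth —
every part of the pipeline is testable end-to-end against that truth.
See `docs/methods.md` for models, parameters and limitations.

## Worked example

Generate a synthetic strain pair (3 × 500 kb, ~225 TE copies, 5 planted
intrachromosomal + 5 interchromosomal movements, 3 decoys of each class),
then track:

```sh
tetrack simulate --out demo/sim --seed 7
tetrack track \
    --ref demo/sim/ref.fa --query demo/sim/query.fa \
    --ref-te demo/sim/ref_te.gff3 --query-te demo/sim/query_te.gff3 \
    --vcf demo/sim/variants.vcf --out demo/track
```

The track command prints the per-family movement table:

```
     family  inter  intra
        CMC      0      1
      Copia      1      0
      Gypsy      0      0
   Helitron      0      1
       MITE      0      2
    Novosib      0      0
       Sola      0      0
Tc1/Mariner      1      0
      Zator      2      1
        hAT      1      0
      Total      5      5
```

Ten movements — exactly the ten planted in `demo/sim/truth_movements.tsv`,
with the right family split.  `demo/track/movements.tsv` holds the verdict
per tracked copy; the decoys land in their exclusion classes rather than
among the movements:

```
ref_te_id  query_te_ids        verdict                family       expected     observed     distance
te_0024    te_0024;te_0024_dup ambiguous_duplication  Tc1/Mariner  .            .            .
te_0032    te_0032             excluded_nested        Tc1/Mariner  I:279143     I:89303      189840
te_0037    te_0037             excluded_flank         MITE         I:387449     I:298956     88493
```

`te_0024` is present at two query loci (duplication decoy: the data cannot
say which copy is the original), `te_0032` is nested inside a same-family
element, and `te_0037` carries near-identical flanks at both loci.  The
remaining ~180 fingerprinted copies are `unmoved`: observed = expected
coordinate within tolerance.

Enrichment of a variant BED in an annotation BED, within arm/center
workspaces derived from the reference:

```sh
tetrack enrich --variants v.bed --annotations a.bed \
    --ref demo/sim/ref.fa --iterations 20000 --seed 1 --out demo/enrich
```

writes `enrichment.tsv` with one row per (workspace × chromosome):
observed overlap bp, null mean ± SD, log2 fold, empirical and
hypergeometric p — heatmap-ready.

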