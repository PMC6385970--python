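# rouscan

Discovery, curation and size-spectrum analysis of **dispersed (non-tandem)
repeats** in organelle-scale genome sequences — the "repeats of unusual
size" (ROUS) that shape plant mitochondrial genomes.

## The problem

Plant mitochondrial genomes (typically 15 kb–1 Mb, single molecule) carry
abundant non-tandem repeats, from ~50 bp up to tens of kilobases. The
large ones recombine and isomerize the genome; the intermediate ones
recombine under DNA-damage stress. They are inconsistently annotated and
hard to catalogue automatically with general-purpose aligners: when a
repeat has mismatches or more than two copies, raw pairwise self-alignment
output reports overlapping subsets instead of a clean set of repeat
families. `rouscan` finds every dispersed repeat in a genome, curates the
raw alignments into distinct repeat families with every copy located, and
summarises the repeat size spectrum within and across species.

## The method

For a genome *S* of length *L*:

1. **Seeded ungapped self-alignment (both strands).** Every word of length
   *w* (default *w* = 50) is indexed; each pair of loci sharing a word —
   directly or as reverse complements — seeds an alignment. Seeds on one
   (anti-)diagonal are coalesced into maximal exact runs, and each run is
   extended in both directions under match/mismatch scoring
   (+1 / −20 by default). Extension stops when the running score drops
   more than *X* = 2·|penalty| below the best seen, then trims back to the
   best-scoring (longest, on ties) endpoint. An alignment is reported when
   its score *s* = (len − mm)·match + mm·penalty ≥ *w*·match. The
   full-length self-identity is deleted; each unordered interval pair is
   reported once. With this scoring an isolated mismatch flanked by ≥ 20
   matches is bridged, while a central cluster of ≥ 3 mismatches splits a
   duplication into two separately reported repeats — deliberately, since
   central divergence indicates two independent events rather than one
   recent duplication.
2. **Curation into families.** Reciprocal duplicate listings are removed
   by comparing coordinates within each size class; one representative
   sequence is extracted per distinct repeat (reverse-complement–identical
   representatives collapse); and each representative is re-aligned
   against the whole genome to locate **every** copy (full-length
   coverage, ≤ 1 mismatch per 100 bp), because a pairwise self-comparison
   does not report all pairs of a 3+-copy repeat. All copies of a family
   have identical length; overlapping/abutting copies set a tandem flag.
3. **Summaries.** Per genome: a per-copy table, a binned size spectrum
   (default bins 50, 100, 200 … 900, 1000, 2000 … 10000, ≥10000) and a
   GenBank 5-column feature table. Across a directory of genomes: a
   genomes × bins matrix, and per taxonomic group the fraction of species
   with at least one repeat in each size bin.

A synthetic-genome module generates i.i.d. backgrounds (guaranteed free of
chance word collisions) with planted repeat families of known length, copy
number, orientation and mismatch positions, plus a brute-force
every-diagonal oracle aligner; engine-vs-oracle set equality and exact
planted-truth recovery are the package's core correctness checks.

## Worked example

Generate a 100 kb synthetic genome with three planted families and find
them:

```bash
$ rouscan synth --length 100000 --seed 11 \
    --plant 600x2 --plant 300x2:+- --plant 450x3 -o mito_demo
100000 bp genome with 3 planted families -> mito_demo.fasta / mito_demo_truth.tsv

$ rouscan find mito_demo.fasta -o out
synthetic_bg_L100000_seed11: 3 repeat families; largest 600 bp; outputs in out/

$ cat out/mito_demo_copies.tsv
family_id  length  copy_count  copy_index  start  end    strand  mismatches  tandem_flag
R1         600     2           1           28529  29128  +       0           False
R1         600     2           2           29864  30463  +       0           False
R2         450     3           1           50639  51088  +       0           False
R2         450     3           2           64154  64603  +       0           False
R2         450     3           3           66329  66778  +       0           False
R3         300     2           1           16753  17052  +       0           False
R3         300     2           2           46064  46363  -       0           False
```

Families are labelled R1, R2, … by descending length; coordinates are
1-based inclusive and a `-` strand copy is the reverse complement of the
representative. The per-genome summary reports the aggregate numbers:

```json
{
  "genome_id": "synthetic_bg_L100000_seed11",
  "n_families": 3,
  "largest_repeat_bp": 600,
  "total_repeated_bp": 3150,
  "fraction_repeated": 0.0315
}
```

`out/` also contains the repeat FASTA (`>R1 len=600 copies=2` …), the
binned size table, a `.tbl` feature table ready for GenBank annotation
(`repeat_region` features, minus-strand copies as start > end) and a
`manifest.json` recording every parameter of the run.

For many genomes: `rouscan batch genomes/ -o batch_out` (per-genome
outputs plus a combined genomes × size-bins matrix), then
`rouscan groups batch_out/combined_bins.tsv --map groups.tsv` for the
per-group fraction-of-species matrix (optionally `--heatmap fig.png`).
Scoring is adjustable (`-w`, `--match`, `--mismatch`, `--min-score`); a
mismatch penalty milder than −18 triggers a warning because copies of one
repeat may then align at different lengths.

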