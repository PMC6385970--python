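# Methods

## Model and assumptions

`rouscan` treats a dispersed repeat as a set of two or more near-identical
sequence copies at separated locations of a single molecule, discovered by
ungapped local self-alignment. The design assumptions are:

- **Single sequence, modest size.** Inputs are single-molecule genomes in
  the 15 kb–1 Mb range (organelle scale). Multi-record FASTA files are
  rejected in single-genome mode: inter- and intra-chromosomal repeats of
  multi-chromosome genomes need different bookkeeping and are out of
  scope. Algorithms are chosen for exactness, not for chromosome-scale
  throughput.
- **Ungapped alignment.** Recently duplicated or gene-conversion-corrected
  copies are co-linear; indels inside a repeat are treated as evidence of
  two separate repeats, not bridged.
- **Harsh mismatch penalty.** The default scoring (match +1, mismatch −20,
  word size 50, minimum score 50) is deliberately stringent so that
  different copies of one repeat align at identical lengths, which is what
  makes coordinate-based curation sound. Milder penalties are accepted
  (with a warning below −18 is no longer guaranteed) for users examining a
  single genome in more detail.
- **A/C/G/T only.** Ambiguity codes either abort the run (default) or are
  masked to a sentinel that matches nothing, including itself, and that no
  seed or extension may cross.

## Alignment definition

All coordinates are 0-based half-open internally; 1-based inclusive
GenBank/BLAST convention appears only in written files.

**Seeding.** A hash index maps every length-*w* word to its occurrence
offsets. Plus-strand seeds are unordered pairs of occurrences of one word;
minus-strand seeds pair a word with occurrences of its reverse complement
(including a locus with itself for perfect palindromes, which legitimately
produce self-overlapping inverted alignments — these are kept). Seeds on
one diagonal (anti-diagonal for minus) at consecutive offsets are
coalesced, so each maximal exact run contributes exactly one seed and long
exact repeats do not trigger quadratically many extensions; dedup after
extension guarantees correctness regardless.

**Extension.** From each maximal exact run the alignment is extended
outward one position at a time, adding `match_reward` or
`mismatch_penalty`, stopping at a sequence end, a masked residue, or when
the running score falls more than `xdrop` below the best prefix score
seen; the endpoint is then trimmed back to the best-scoring position, with
ties broken toward the longer segment. The default
`xdrop = 2·|mismatch_penalty|` (40 raw units) was chosen over a fully
optimal maximal-scoring-subsegment extension for a scientific reason: an
optimal extension would merge a duplication whose copies differ by a
central cluster of 3+ mismatches into a single alignment whenever enough
matching sequence follows (three mismatches cost 60, recovered by 60
matches), whereas central divergence between copies is evidence of two
independent duplication events or long-escaped gene conversion. The bound
makes the tool report such structures as two repeats, while an isolated
mismatch flanked by ≥ 20 matches is still bridged. Both documented
boundary behaviours — "50 matches, 1 mismatch, 20 matches" extends to 71
bp at score 50, and the same with only 19 trailing matches stops at 50 —
hold under this rule.

**Reporting.** An alignment is kept when its score is at least
`min_score` (default `word_size · match_reward`). This replaces a
BLAST-style E-value reporting cutoff: with +1/−20 scoring any alignment at
score ≥ *w* necessarily contains an exact core of ≥ *w* matches, making
the minimum score the natural, parameter-free surrogate. The full-length
self-identity is deleted, each unordered interval pair appears once
(canonical orientation: query interval lexicographically ≤ subject
interval), and output order is descending score then coordinates, so runs
are byte-reproducible.

**Circular mode** (off by default): the sequence is conceptually doubled;
alignments whose query start lies beyond the original length are
discarded as duplicate images, no alignment may exceed the original
length, and origin-spanning copies report an end coordinate past *L* with
wrap implied. Tandem adjacency across the origin is not flagged.

## Curation rules

1. **Duplicate removal.** Within each size class, listings whose
   query/subject interval pairs coincide (in either order) collapse to
   one.
2. **Representatives.** Each remaining alignment contributes its
   query-interval subsequence; identical or reverse-complement-identical
   sequences collapse.
3. **Second pass.** Each representative is aligned against the whole
   genome on both strands. A location is a copy iff the representative is
   covered **full-length** with at most ⌊length/100⌋ mismatches
   (configurable rate, default 1 per 100 bp — the scoring's break-even,
   where one mismatch costs 20 matches). Full-length coverage is what
   preserves copy-length homogeneity within a family; whether partial
   hits should ever count is genuinely open, and the rule is exposed as a
   parameter rather than hidden.
4. **Merging.** Families with identical copy sets merge; same-length
   families sharing any copy location merge (union of copies). Merging is
   by coordinates, never by sequence-similarity clustering.
5. **Labels and flags.** Families are labelled R1, R2, … by descending
   length (ties: ascending first-copy start, then representative
   sequence). A family whose copies overlap or abut anywhere is flagged
   tandem but kept — tandem arrays are real structures worth reporting;
   the flag lets users filter. Copy strands are relative: the
   representative is the first plus-strand copy's genome text (or the
   reverse complement of the first copy if all copies are minus), and two
   "inverted" copies of each other are reported as one + and one − copy.
   A representative with fewer than two located copies (possible only for
   pathological inputs) is dropped with a logged warning.

## Summary statistics

- **Size bins** are right-open `[a, b)` with an unbounded last bin; a
  repeat of exactly 200 bp counts in the bin starting at 200. Default
  edges 50, 100, 200…900, 1000, 2000…10000 span the biologically observed
  range; they are a declared default, configurable per run.
- **Per-genome summary**: family count, largest repeat, total repeated bp
  (Σ length·copies) and repeated fraction of the genome.
- **Group matrix**: per taxon group and bin, the fraction k/n of the
  group's species with ≥ 1 family in the bin. Presence/absence per bin is
  used because total repeat counts vary by an order of magnitude between
  species.
- Batch runs process files in sorted filename order and isolate per-genome
  failures; outputs are deterministic and rerun-identical.

## Synthetic data: what it emulates and what it does not

The generator produces i.i.d. backgrounds with configurable GC (default
0.45, typical of plant mitochondrial DNA) and rejects any background
containing a duplicated, reverse-complement-shared or palindromic word of
the seed length — at 4⁻⁵⁰ collision rates this essentially never
triggers, but it makes planted truth sets exact by construction. Planted
families have fresh random repeat units, chosen orientations, explicit or
random non-overlapping placements (10 bp minimum gap; abutting copies
only via explicit starts, for tandem tests), and per-copy substitutions
at stated unit offsets. The single background base flanking each copy is
forced to mismatch, diagonal-adjusted, the corresponding flank of every
other copy (guaranteed satisfiable up to 4 copies), so alignments end
exactly at planted boundaries instead of gaining a geometrically
distributed few bp of chance flank matches; recorded truth is therefore
exact, and recovery tests can assert equality rather than tolerance.
Random mismatch placement keeps substitutions ≥ 25 bp from the ends and
from each other so each stays individually bridgeable.

What the fixtures do **not** emulate: real mitochondrial base composition
structure (genes, low-complexity tracts, microsatellites), nested and
overlapping repeat structures, degraded ancient repeats with indels, or
multipartite genome organisation. Passing the synthetic suite shows the
algorithm is exact under its own model — identical to the brute-force
oracle and faithful to planted truth — not that curation choices (e.g.
the full-length second-pass rule) match any particular hand-curated
catalogue of a real genome.

The oracle aligner scans every diagonal and anti-diagonal exhaustively
(quadratic; guarded to ≤ 20 kb) and applies the same alignment definition
through independent code; it is the reference the engine is tested
against, never a component of the pipeline.

## Numerical and degenerate-input choices

- Deterministic throughout: no randomness in the pipeline; generator
  randomness is fully seeded (NumPy `default_rng`).
- Tie-breaks: equal-score extension endpoints go to the longer segment;
  family ordering is total (length, first start, representative), so all
  outputs are diff-stable.
- Degenerate inputs: empty family lists produce valid empty outputs;
  zero-length or multi-record FASTA, out-of-range feature coordinates,
  non-increasing bin edges, genomes missing from the group map, and
  representatives shorter than the word size all raise named errors.
- Problem sizes in the test and acceptance runs (backgrounds of 1.5–20 kb
  for oracle comparisons, 100 kb for null checks; 40–100 random fixtures)
  were chosen so the quadratic oracle remains the bottleneck-free
  referee while still exercising every code path; the engine itself
  handles 1 Mb genomes in seconds.

## Known limitations

- Boundary placement intentionally differs from heuristic aligners such
  as blastn by up to a few bp at diverged repeat edges (X-drop bound and
  trimming rule differ); exact repeats agree exactly, which is what the
  blastn cross-check asserts. The `outfmt 6` parser lets users diff
  against their own blastn runs.
- Gapped divergence between copies always splits a repeat; there is no
  option to bridge indels.
- The second-pass copy criterion (full-length, ≤ 1 mismatch/100 bp) can
  miss heavily diverged outlier copies that a looser, partial-coverage
  rule would count.
- Circular mode does not flag tandem adjacency across the origin and
  reports origin-spanning copies with coordinates past the sequence
  length.
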