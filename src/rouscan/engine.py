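"""Ungapped self-alignment of a genome on both strands.

The engine replaces a blastn self-comparison with an exact method:
every duplicated word of length ``word_size`` seeds an alignment
(k-mer index), seeds on one diagonal are coalesced into maximal exact
runs, and each run is extended in both directions under match/mismatch
scoring with an X-drop bound. With the default scoring (+1/-20, word 50)
any reported alignment necessarily contains a >= 50 bp exact core, which
makes a minimum reported score of ``word_size`` the natural surrogate
for blastn's E-value reporting cutoff.

The X-drop bound (default ``2 * |mismatch_penalty|``) lets an extension
bridge isolated mismatches flanked by enough matching sequence, while a
cluster of mismatches whose combined penalty exceeds the bound splits
the duplication into two separately reported repeats -- the behaviour
the curation stage relies on to keep repeat copies the same length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import GenomeSequence, MASK_CODE, reverse_complement

__all__ = [
    "Scoring",
    "SeedMatch",
    "HSP",
    "SeedIndex",
    "build_seed_index",
    "enumerate_seed_matches",
    "extend_ungapped",
    "self_compare",
    "read_blast_tabular",
]


@dataclass(frozen=True)
class Scoring:
    """Alignment parameter set.

    Parameters
    ----------
    word_size :
        Minimum exact-match seed length (bp). Default 50.
    match_reward, mismatch_penalty :
        Per-residue scores; defaults +1 / -20. A penalty of -18 or lower
        keeps different copies of a repeat the same length under the
        curation rules; milder penalties are accepted but the caller is
        warned by the CLI.
    min_score :
        Minimum reported alignment score. Defaults to
        ``word_size * match_reward``.
    xdrop :
        Extension stops once the running score falls more than this many
        raw score units below the best score seen, then trims back to
        the best. Defaults to ``2 * |mismatch_penalty|``.
    """

    word_size: int = 50
    match_reward: int = 1
    mismatch_penalty: int = -20
    min_score: int | None = None
    xdrop: int | None = None

    def __post_init__(self) -> None:
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0:
            raise ValueError("mismatch_penalty must be negative")
        if self.min_score is not None and self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.xdrop is not None and self.xdrop < 0:
            raise ValueError("xdrop must be >= 0")

    @property
    def effective_min_score(self) -> int:
        return self.word_size * self.match_reward if self.min_score is None else self.min_score

    @property
    def effective_xdrop(self) -> int:
        return 2 * abs(self.mismatch_penalty) if self.xdrop is None else self.xdrop


@dataclass(frozen=True)
class SeedMatch:
    """A coalesced exact match between two genome loci.

    ``q_pos``/``s_pos`` are 0-based starts of the two matched intervals;
    ``span`` is the length of the maximal exact run (>= word_size). On
    the minus strand the intervals match as reverse complements and lie
    on one anti-diagonal (q_pos + s_pos + span - 1 constant).
    """

    q_pos: int
    s_pos: int
    strand: str
    span: int


@dataclass(frozen=True, order=True)
class HSP:
    """One ungapped local alignment between two genome intervals.

    Coordinates are 0-based half-open. ``strand`` is '+' when both
    intervals read the same sequence and '-' when the subject interval
    is the reverse complement of the query interval. Canonical
    orientation: (q_start, q_end) <= (s_start, s_end).
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


class SeedIndex:
    """Exact k-mer index of a genome: word -> sorted occurrence offsets.

    Words containing a masked residue are absent. Reverse-complement
    queries go through :meth:`occurrences` on the complemented word.
    """

    def __init__(self, words: dict[str, list[int]], word_size: int) -> None:
        self.words = words
        self.word_size = word_size

    def occurrences(self, word: str) -> list[int]:
        return self.words.get(word, [])

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)


def build_seed_index(genome: GenomeSequence, word_size: int) -> SeedIndex:
    """Index every word of length ``word_size`` in the genome."""
    L = len(genome)
    if word_size > L:
        raise ValueError(f"word_size {word_size} exceeds genome length {L}")
    seq = genome.seq
    words: dict[str, list[int]] = defaultdict(list)
    if "N" not in seq:
        for i in range(L - word_size + 1):
            words[seq[i:i + word_size]].append(i)
    else:
        # positions whose word would cross a masked residue are skipped
        codes = genome.codes()
        bad = np.flatnonzero(codes == MASK_CODE)
        blocked = np.zeros(L - word_size + 1, dtype=bool)
        for p in bad:
            blocked[max(0, p - word_size + 1):p + 1] = True
        for i in np.flatnonzero(~blocked):
            i = int(i)
            words[seq[i:i + word_size]].append(i)
    return SeedIndex(dict(words), word_size)


def _coalesce(starts: list[int], word_size: int) -> list[tuple[int, int]]:
    """Merge consecutive seed starts on one (anti-)diagonal into maximal
    exact runs; returns (start, span) pairs."""
    runs = []
    starts = sorted(set(starts))
    lo = prev = starts[0]
    for x in starts[1:]:
        if x == prev + 1:
            prev = x
        else:
            runs.append((lo, prev - lo + word_size))
            lo = prev = x
    runs.append((lo, prev - lo + word_size))
    return runs


def enumerate_seed_matches(index: SeedIndex, genome: GenomeSequence) -> list[SeedMatch]:
    """All non-trivial word matches, coalesced per diagonal.

    Plus strand: every unordered pair of occurrences of one word
    (the trivial q == s self-match never arises). Minus strand: every
    pair of loci where one word is the reverse complement of the other,
    including a locus against itself for perfect palindromes. Each
    maximal exact run contributes exactly one seed.
    """
    w = index.word_size
    plus: dict[int, list[int]] = defaultdict(list)
    minus: dict[int, list[int]] = defaultdict(list)
    for word, occ in index.words.items():
        if len(occ) > 1:
            for i, a in enumerate(occ):
                for b in occ[i + 1:]:
                    plus[b - a].append(a)
        rc = reverse_complement(word)
        if rc < word or rc not in index:
            continue
        if rc == word:
            pairs = [(a, b) for i, a in enumerate(occ) for b in occ[i:]]
        else:
            other = index.words[rc]
            pairs = [(min(a, b), max(a, b)) for a in occ for b in other]
        for a, b in pairs:
            minus[a + b + w - 1].append(a)

    seeds: list[SeedMatch] = []
    for d in sorted(plus):
        for start, span in _coalesce(plus[d], w):
            seeds.append(SeedMatch(q_pos=start, s_pos=start + d, strand="+", span=span))
    for c in sorted(minus):
        for start, span in _coalesce(minus[c], w):
            # partner interval of q=[start, start+span) on anti-diagonal c
            seeds.append(SeedMatch(q_pos=start, s_pos=c - start - span + 1,
                                   strand="-", span=span))
    return seeds


def _xdrop_walk(match_state, start: int, stop: int, step: int,
                reward: int, penalty: int, xdrop: int) -> int:
    """Walk outward from a seed boundary; return the last index kept.

    ``match_state(i)`` is True (match), False (mismatch) or None
    (barrier: masked residue or out of range). Ties at equal best score
    extend the boundary (longest segment wins).
    """
    delta = best = 0
    best_i = start - step
    i = start
    while (i <= stop) if step > 0 else (i >= stop):
        state = match_state(i)
        if state is None:
            break
        delta += reward if state else penalty
        if delta >= best:
            best = delta
            best_i = i
        elif best - delta > xdrop:
            break
        i += step
    return best_i


def extend_ungapped(genome: GenomeSequence, seed: SeedMatch, scoring: Scoring) -> HSP | None:
    """Extend a seed to its X-drop-bounded maximal segment on the diagonal.

    Returns None when the final score falls below ``min_score``.
    Extension never crosses a sequence end or a masked residue.
    """
    codes = genome.codes()
    L = len(genome)
    rew, pen = scoring.match_reward, scoring.mismatch_penalty
    xd = scoring.effective_xdrop

    if seed.strand == "+":
        d = seed.s_pos - seed.q_pos

        def match_state(i: int):
            j = i + d
            if i < 0 or j >= L:
                return None
            a, b = codes[i], codes[j]
            if a == MASK_CODE or b == MASK_CODE:
                return None
            return bool(a == b)

        lo_limit, hi_limit = 0, L - 1 - d
    else:
        c = seed.q_pos + seed.s_pos + seed.span - 1

        def match_state(i: int):
            j = c - i
            if i < 0 or j < 0 or i >= L or j >= L:
                return None
            a, b = codes[i], codes[j]
            if a == MASK_CODE or b == MASK_CODE:
                return None
            return bool(a == 3 - b)

        lo_limit, hi_limit = max(0, c - (L - 1)), min(L - 1, c)

    q0 = _xdrop_walk(match_state, seed.q_pos - 1, lo_limit, -1, rew, pen, xd)
    q1 = _xdrop_walk(match_state, seed.q_pos + seed.span, hi_limit, +1, rew, pen, xd) + 1
    length = q1 - q0

    if seed.strand == "+":
        s0, s1 = q0 + d, q1 + d
        mism = int(np.count_nonzero(codes[q0:q1] != codes[s0:s1]))
    else:
        s0, s1 = c - q1 + 1, c - q0 + 1
        mism = int(np.count_nonzero(codes[q0:q1] != (3 - codes[s0:s1])[::-1]))

    score = rew * (length - mism) + pen * mism
    if score < scoring.effective_min_score:
        return None
    if (s0, s1) < (q0, q1):
        q0, q1, s0, s1 = s0, s1, q0, q1
    return HSP(q0, q1, s0, s1, seed.strand, score, mism)


def _sorted_hsps(hsps: set[HSP]) -> list[HSP]:
    return sorted(hsps, key=lambda h: (-h.score, h.q_start, h.q_end,
                                       h.s_start, h.s_end, h.strand))


def self_compare(genome: GenomeSequence, scoring: Scoring | None = None,
                 circular: bool | None = None) -> list[HSP]:
    """All distinct ungapped self-alignments of a genome, both strands.

    The full-length self-identity is never reported. Output is sorted by
    descending score, then coordinates; identical interval pairs appear
    once. In circular mode the sequence is conceptually doubled so that
    alignments may span the origin; duplicate images from the doubling
    are removed and no alignment may exceed the original length.
    """
    scoring = scoring or Scoring()
    if circular is None:
        circular = genome.circular
    if not circular:
        return _sorted_hsps(_self_compare_linear(genome, scoring))

    L = len(genome)
    doubled = GenomeSequence(id=genome.id, seq=genome.seq * 2)
    out: set[HSP] = set()
    for h in _self_compare_linear(doubled, scoring):
        if h.length > L or h.q_start >= L:
            continue
        q0, q1, s0, s1 = h.q_start, h.q_end, h.s_start, h.s_end
        if s0 >= L:
            s0, s1 = s0 - L, s1 - L
        if (s0, s1) < (q0, q1):
            q0, q1, s0, s1 = s0, s1, q0, q1
        if (q0, q1) == (s0, s1) and h.strand == "+":
            continue  # image of the self-identity across the junction
        out.add(HSP(q0, q1, s0, s1, h.strand, h.score, h.mismatches))
    return _sorted_hsps(out)


def _self_compare_linear(genome: GenomeSequence, scoring: Scoring) -> set[HSP]:
    index = build_seed_index(genome, scoring.word_size)
    out: set[HSP] = set()
    L = len(genome)
    for seed in enumerate_seed_matches(index, genome):
        h = extend_ungapped(genome, seed, scoring)
        if h is None:
            continue
        if h.strand == "+" and h.q_start == h.s_start and h.length == L:
            continue  # full-length self-identity
        out.add(h)
    return out


# 12 standard outfmt-6 columns, for cross-validation against blastn runs
_BLAST6_COLS = ("qseqid sseqid pident length mismatch gapopen "
                "qstart qend sstart send evalue bitscore").split()


def read_blast_tabular(path: str | Path, scoring: Scoring | None = None) -> list[HSP]:
    """Parse NCBI blastn ``-outfmt 6`` output into canonical HSPs.

    Gapped rows are dropped (the engine is ungapped), as are full-length
    self-identity rows and reciprocal duplicate listings. Raw scores are
    recomputed from length and mismatch count under ``scoring``
    (default +1/-20), since outfmt 6 carries only bitscores.
    """
    scoring = scoring or Scoring()
    out: set[tuple] = set()
    hsps: set[HSP] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = dict(zip(_BLAST6_COLS, line.split("\t")))
        if int(cols["gapopen"]) != 0:
            continue
        q0, q1 = int(cols["qstart"]) - 1, int(cols["qend"])
        s_a, s_b = int(cols["sstart"]), int(cols["send"])
        if s_a <= s_b:
            strand, s0, s1 = "+", s_a - 1, s_b
        else:
            strand, s0, s1 = "-", s_b - 1, s_a
        if strand == "+" and (q0, q1) == (s0, s1):
            continue  # self-identity
        if (s0, s1) < (q0, q1):
            q0, q1, s0, s1 = s0, s1, q0, q1
        key = (q0, q1, s0, s1, strand)
        if key in out:
            continue
        out.add(key)
        mism = int(cols["mismatch"])
        length = int(cols["length"])
        score = scoring.match_reward * (length - mism) + scoring.mismatch_penalty * mism
        hsps.add(HSP(q0, q1, s0, s1, strand, score, mism))
    return _sorted_hsps(hsps)
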