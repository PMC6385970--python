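"""From raw self-alignments to curated repeat families.

The curation premise is that, under a sufficiently harsh mismatch
penalty, different copies of one repeat align at identical length, so
repeats can be matched purely by size and coordinates: reciprocal
listings of the same alignment are removed, one representative sequence
is extracted per distinct repeat, and a second alignment pass of each
representative against the whole genome locates every copy (a pairwise
self-comparison does not report all pairs when a repeat has more than
two copies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .engine import HSP, Scoring, SeedIndex, build_seed_index
from .seqio import GenomeSequence, MASK_CODE, reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "RepeatCopy",
    "RepeatFamily",
    "deduplicate_hsps",
    "select_representatives",
    "locate_all_copies",
    "build_families",
    "find_repeats",
]


@dataclass(frozen=True, order=True)
class RepeatCopy:
    """One genomic copy of a repeat (0-based half-open internally)."""

    start: int
    end: int
    strand: str
    mismatches_vs_representative: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatFamily:
    """One distinct repeated sequence and every genomic copy of it.

    All copies have the same length (the curation premise). The
    representative is the genome subsequence of the first plus-strand
    copy, or the reverse complement of the first copy if all copies are
    on the minus strand. ``tandem_flag`` marks families in which any two
    copies overlap or abut.
    """

    family_id: str
    length: int
    representative: str
    copies: list[RepeatCopy]
    tandem_flag: bool = False

    @property
    def copy_number(self) -> int:
        return len(self.copies)


def deduplicate_hsps(hsps: list[HSP]) -> list[HSP]:
    """Remove reciprocal/duplicate listings of one aligned interval pair.

    Alignments are grouped by size; within a size class two listings are
    duplicates when the query interval of one matches the subject
    interval of the other and vice versa (or they are simply identical).
    """
    seen: set[tuple] = set()
    out: list[HSP] = []
    for h in sorted(hsps, key=lambda h: (-h.length, h.q_start, h.s_start, h.strand)):
        a, b = (h.q_start, h.q_end), (h.s_start, h.s_end)
        key = (min(a, b), max(a, b), h.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    return out


def select_representatives(hsps: list[HSP], genome: GenomeSequence) -> list[str]:
    """One sequence per distinct repeat.

    For each deduplicated alignment the query-interval subsequence is
    taken; sequences that are identical or reverse-complement identical
    are collapsed to one.
    """
    seen: set[str] = set()
    reps: list[str] = []
    for h in sorted(hsps, key=lambda h: (-h.length, h.q_start, h.s_start)):
        seq = genome.seq[h.q_start:h.q_end]
        key = min(seq, reverse_complement(seq))
        if key in seen:
            continue
        seen.add(key)
        reps.append(seq)
    return reps


def locate_all_copies(representative: str, genome: GenomeSequence,
                      scoring: Scoring | None = None,
                      index: SeedIndex | None = None,
                      max_mismatch_rate: float = 0.01) -> RepeatFamily:
    """Locate every genomic copy of a repeat representative.

    A genome location counts as a copy iff the representative aligns
    there over its full length with at most
    ``floor(length * max_mismatch_rate)`` mismatches (default: one
    mismatch per 100 bp, mirroring the scoring's break-even where one
    mismatch costs 20 matches). Full-length coverage keeps all copies of
    a family the same length. Copies are sorted by start. Families with
    a single copy are returned un-labelled for the caller to drop.
    """
    scoring = scoring or Scoring()
    R = len(representative)
    if R < scoring.word_size:
        raise ValueError(
            f"representative length {R} is shorter than word_size {scoring.word_size}"
        )
    if index is None:
        index = build_seed_index(genome, scoring.word_size)
    max_mm = int(R * max_mismatch_rate)
    L = len(genome)
    codes = genome.codes()

    def _candidates(query: str) -> set[int]:
        w = index.word_size
        cands: set[int] = set()
        for off in range(0, R - w + 1):
            for p in index.occurrences(query[off:off + w]):
                t = p - off
                if 0 <= t <= L - R:
                    cands.add(t)
        return cands

    def _encode(s: str) -> np.ndarray:
        from .seqio import _CODE_TABLE
        return _CODE_TABLE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]

    copies: list[RepeatCopy] = []
    taken: set[tuple[int, int]] = set()
    for strand, query in (("+", representative), ("-", reverse_complement(representative))):
        qc = _encode(query)
        for t in sorted(_candidates(query)):
            window = codes[t:t + R]
            if np.any(window == MASK_CODE) or np.any(qc == MASK_CODE):
                continue
            mm = int(np.count_nonzero(window != qc))
            if mm <= max_mm and (t, t + R) not in taken:
                taken.add((t, t + R))
                copies.append(RepeatCopy(t, t + R, strand, mm))
    copies.sort(key=lambda c: (c.start, c.end, c.strand))
    return RepeatFamily(family_id="", length=R, representative=representative,
                        copies=copies, tandem_flag=_is_tandem(copies))


def _is_tandem(copies: list[RepeatCopy]) -> bool:
    """True when any two copies overlap or abut (gap of zero)."""
    ordered = sorted(copies, key=lambda c: c.start)
    return any(b.start <= a.end for a, b in zip(ordered, ordered[1:]))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_families(hsps: list[HSP], genome: GenomeSequence,
                   scoring: Scoring | None = None,
                   max_mismatch_rate: float = 0.01) -> list[RepeatFamily]:
    """Full curation pipeline: dedup -> representatives -> locate copies.

    Families whose copy sets are identical are merged, as are
    same-length families sharing any copy location. Family ids R1, R2,
    ... are assigned by descending length (ties: ascending first-copy
    start, then representative sequence). Single-copy leftovers are
    dropped with a warning.
    """
    scoring = scoring or Scoring()
    uniq = deduplicate_hsps(hsps)
    reps = select_representatives(uniq, genome)
    index = build_seed_index(genome, scoring.word_size) if reps else None

    raw: list[RepeatFamily] = []
    for rep in reps:
        fam = locate_all_copies(rep, genome, scoring, index=index,
                                max_mismatch_rate=max_mismatch_rate)
        if len(fam.copies) < 2:
            log.warning(
                "representative of length %d has %d genomic location(s); "
                "a repeat needs at least 2 copies -- dropped",
                fam.length, len(fam.copies),
            )
            continue
        raw.append(fam)

    # merge families with identical copy sets, and same-length families
    # sharing any copy location
    uf = _UnionFind(len(raw))
    loc_owner: dict[tuple, int] = {}
    for i, fam in enumerate(raw):
        for c in fam.copies:
            key = (c.start, c.end, fam.length)
            if key in loc_owner:
                uf.union(loc_owner[key], i)
            else:
                loc_owner[key] = i

    grouped: dict[int, list[RepeatFamily]] = {}
    for i, fam in enumerate(raw):
        grouped.setdefault(uf.find(i), []).append(fam)

    merged: list[RepeatFamily] = []
    for members in grouped.values():
        base = members[0]
        locs: dict[tuple[int, int], RepeatCopy] = {}
        for fam in members:
            for c in fam.copies:
                locs.setdefault((c.start, c.end), c)
        copies = sorted(locs.values(), key=lambda c: c.start)
        merged.append(_finalize(base.length, copies, genome))

    merged.sort(key=lambda f: (-f.length, f.copies[0].start, f.representative))
    for rank, fam in enumerate(merged, start=1):
        fam.family_id = f"R{rank}"
    return merged


def _finalize(length: int, copies: list[RepeatCopy], genome: GenomeSequence) -> RepeatFamily:
    """Fix the representative to the first plus-strand copy (or the
    reverse complement of the first copy when all are minus) and rebase
    per-copy mismatch counts against it."""
    plus = [c for c in copies if c.strand == "+"]
    if plus:
        rep = genome.seq[plus[0].start:plus[0].end]
    else:
        rep = reverse_complement(genome.seq[copies[0].start:copies[0].end])
    rebased: list[RepeatCopy] = []
    for c in copies:
        seq = genome.seq[c.start:c.end]
        if c.strand == "-":
            seq = reverse_complement(seq)
        mm = sum(1 for a, b in zip(rep, seq) if a != b)
        rebased.append(RepeatCopy(c.start, c.end, c.strand, mm))
    return RepeatFamily(family_id="", length=length, representative=rep,
                        copies=rebased, tandem_flag=_is_tandem(rebased))


def find_repeats(genome: GenomeSequence, scoring: Scoring | None = None,
                 circular: bool | None = None,
                 max_mismatch_rate: float = 0.01) -> list[RepeatFamily]:
    """End-to-end repeat discovery: self-comparison plus curation.

    In circular mode curation runs on the conceptually doubled sequence
    so copies spanning the origin are located; such copies report an end
    coordinate past the sequence length (wrap implied), and each copy is
    reported once (duplicate images from the doubling are removed).
    """
    from .engine import self_compare

    scoring = scoring or Scoring()
    if circular is None:
        circular = genome.circular
    hsps = self_compare(genome, scoring, circular=circular)
    if not circular:
        return build_families(hsps, genome, scoring, max_mismatch_rate=max_mismatch_rate)

    L = len(genome)
    doubled = GenomeSequence(id=genome.id, seq=genome.seq * 2)
    fams = build_families(hsps, doubled, scoring, max_mismatch_rate=max_mismatch_rate)
    out: list[RepeatFamily] = []
    for fam in fams:
        if fam.length >= L:
            continue
        copies = [c for c in fam.copies if c.start < L]
        if len(copies) < 2:
            continue
        out.append(_finalize(fam.length, copies, doubled))
    out.sort(key=lambda f: (-f.length, f.copies[0].start, f.representative))
    for rank, fam in enumerate(out, start=1):
        fam.family_id = f"R{rank}"
    return out
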