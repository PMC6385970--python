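"""Synthetic genomes with planted repeat structure, and a brute-force
oracle aligner.

The generator realises the random-sequence null model: an i.i.d.
background of configurable length and GC content in which, at word
size 50, two identical (or reverse-complement identical) 50-mers
essentially never arise by chance (collision probability ~ L^2 * 4^-50,
about 1e-20 at 100 kb). Repeat families of known length, copy number,
orientation and per-copy mismatch positions are then written into the
background, and the exact coordinates are recorded as a truth set.

The oracle scans every diagonal (and anti-diagonal, for the minus
strand) of the genome against itself exhaustively -- quadratic, so it
is guarded to small inputs -- and applies the same alignment definition
as the engine. Engine/oracle set equality on such genomes is the
package's core correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import HSP, Scoring
from .seqio import GenomeSequence, MASK_CODE, reverse_complement

__all__ = [
    "PlantSpec",
    "TruthFamily",
    "TruthSet",
    "generate_background",
    "plant_family",
    "make_fixture",
    "oracle_self_compare",
    "sample_mismatch_offsets",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """Specification of one repeat family to plant.

    ``orientations`` defaults to all '+'; ``mismatches`` gives, per
    copy, the offsets (in repeat-unit coordinates) at which that copy is
    substituted; ``starts`` pins explicit 0-based placements (otherwise
    placement is random and non-overlapping).
    """

    length: int
    n_copies: int = 2
    orientations: tuple[str, ...] | None = None
    mismatches: tuple[tuple[int, ...], ...] | None = None
    starts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_copies < 2:
            raise ValueError("a planted family needs length >= 1 and >= 2 copies")
        if self.orientations is not None and len(self.orientations) != self.n_copies:
            raise ValueError("one orientation per copy required")
        if self.orientations is not None and set(self.orientations) - {"+", "-"}:
            raise ValueError("orientations must be '+' or '-'")
        if self.mismatches is not None:
            if len(self.mismatches) != self.n_copies:
                raise ValueError("one mismatch tuple per copy required")
            for offs in self.mismatches:
                if any(not 0 <= o < self.length for o in offs):
                    raise ValueError("mismatch offsets must lie within the repeat")
        if self.starts is not None and len(self.starts) != self.n_copies:
            raise ValueError("one start per copy required")

    @property
    def orient(self) -> tuple[str, ...]:
        return self.orientations or ("+",) * self.n_copies

    @property
    def mm(self) -> tuple[tuple[int, ...], ...]:
        return self.mismatches or ((),) * self.n_copies


@dataclass
class TruthFamily:
    length: int
    copies: list[tuple[int, int, str, int]]  # (start, end, strand, mismatches)


@dataclass
class TruthSet:
    families: list[TruthFamily] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["family\tcopy\tstart\tend\tstrand\tmismatches"]
        for i, fam in enumerate(self.families, start=1):
            for k, (s, e, strand, mm) in enumerate(fam.copies, start=1):
                lines.append(f"F{i}\t{k}\t{s + 1}\t{e}\t{strand}\t{mm}")
        Path(path).write_text("\n".join(lines) + "\n")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in draws)


def _has_self_repeat(seq: str, word_size: int) -> bool:
    """Any duplicated word, reverse-complement word pair, or palindromic
    word -- i.e. anything that could seed a spurious self-alignment."""
    seen: set[str] = set()
    rc_seen: set[str] = set()
    for i in range(len(seq) - word_size + 1):
        word = seq[i:i + word_size]
        if word in seen or word in rc_seen:
            return True
        rc = reverse_complement(word)
        if rc == word:
            return True
        seen.add(word)
        rc_seen.add(rc)
    return False


def generate_background(length: int, gc: float = 0.45, seed: int = 0,
                        word_size: int = 50, max_tries: int = 10) -> GenomeSequence:
    """i.i.d. random genome with P(G) + P(C) = gc, free of self-repeats.

    Any background containing a duplicated or palindromic word of
    ``word_size`` is regenerated (at 4^-50 collision rates this
    essentially never triggers, but it makes planted truth sets exact
    by construction). Deterministic given the seed.
    """
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seq = _random_seq(rng, length, gc)
        if length < word_size or not _has_self_repeat(seq, word_size):
            return GenomeSequence(id=f"synthetic_bg_L{length}_seed{seed}", seq=seq)
    raise RuntimeError("could not generate a self-repeat-free background")


def sample_mismatch_offsets(length: int, k: int, rng: np.random.Generator,
                            margin: int = 25, min_sep: int = 25) -> tuple[int, ...]:
    """k interior mismatch offsets, kept >= margin from the repeat ends
    and >= min_sep apart so each substitution stays bridgeable by the
    default extension (one mismatch costs 20 matches to recover)."""
    if k == 0:
        return ()
    if length < 2 * margin + (k - 1) * min_sep:
        raise ValueError(f"repeat of {length} bp too short for {k} spaced mismatches")
    while True:
        offs = sorted(int(x) for x in rng.integers(margin, length - margin, size=k))
        if all(b - a >= min_sep for a, b in zip(offs, offs[1:])):
            return tuple(offs)


def plant_family(genome: GenomeSequence, spec: PlantSpec,
                 seed: int = 0) -> tuple[GenomeSequence, TruthSet]:
    """Write one repeat family into a background genome.

    The repeat unit is a fresh random sequence; copies are placed at the
    spec's explicit starts or at random non-overlapping positions, the
    minus-strand copies as reverse complements, and per-copy mismatches
    substituted (uniformly among the 3 alternative bases) at the stated
    unit offsets. The background bases immediately flanking each copy
    are forced to mismatch across every copy pair (diagonal-adjusted),
    so alignments end exactly at the planted boundaries and the truth
    set is exact rather than subject to random flanking matches.
    Returns the modified genome and the exact truth set.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    R = spec.length
    if R > L:
        raise ValueError("planted repeat longer than genome")

    unit = _random_seq(rng, R, 0.5)
    while R >= 50 and _has_self_repeat(unit, 50):  # pragma: no cover - ~4^-50
        unit = _random_seq(rng, R, 0.5)

    if spec.starts is not None:
        starts = list(spec.starts)
        if any(not 0 <= s <= L - R for s in starts):
            raise ValueError("explicit placement outside the genome")
        ivs = sorted((s, s + R) for s in starts)
        # abutting copies are allowed (tandem tests); true overlap is not
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping explicit placements {ivs}")
    else:
        starts = _place(rng, L, R, spec.n_copies, occupied=[])

    seq = bytearray(genome.seq, "ascii")
    truth = TruthFamily(length=R, copies=[])
    for k in range(spec.n_copies):
        start, strand = starts[k], spec.orient[k]
        copy = unit if strand == "+" else reverse_complement(unit)
        seq[start:start + R] = copy.encode("ascii")
        for off in spec.mm[k]:
            pos = start + off if strand == "+" else start + (R - 1 - off)
            old = chr(seq[pos])
            seq[pos] = ord(rng.choice([b for b in _BASES if b != old]))
        truth.copies.append((start, start + R, strand, len(spec.mm[k])))
    _insulate_flanks(seq, starts, spec.orient, R, rng)
    truth.copies.sort(key=lambda c: c[0])
    # orientation is only observable relative to the other copies (two
    # minus-strand copies carry the same string): record strands
    # relative to the first copy, which is '+' by convention
    ref = truth.copies[0][2]
    truth.copies = [(s, e, "+" if st == ref else "-", mm)
                    for s, e, st, mm in truth.copies]
    out = GenomeSequence(id=genome.id, seq=seq.decode("ascii"),
                         circular=genome.circular)
    return out, TruthSet([truth])


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _insulate_flanks(seq: bytearray, starts: list[int], orient: tuple[str, ...],
                     R: int, rng: np.random.Generator) -> None:
    """Force the base just outside each planted copy to mismatch, on the
    relevant (anti-)diagonal, the base just outside every other copy.

    For same-orientation copies i, j the left-outside bases pair with
    each other (likewise right-outside); for opposite orientations the
    left-outside base of i pairs with the complement of the
    right-outside base of j. Flank slots at a sequence end, or falling
    inside another copy (abutting/tandem placements), are skipped.
    Guaranteed satisfiable for up to 4 copies; best-effort beyond.
    """
    L = len(seq)
    ivs = [(s, s + R) for s in starts]

    def slot_ok(pos: int) -> bool:
        return 0 <= pos < L and not any(a <= pos < b for a, b in ivs)

    chosen: dict[int, str] = {}  # slot position -> base

    def assign(pos: int, forbidden: set[str]) -> None:
        options = [b for b in _BASES if b not in forbidden]
        if not options:  # > 4 copies: best effort
            options = list(_BASES)
        base = options[int(rng.integers(0, len(options)))]
        chosen[pos] = base
        seq[pos] = ord(base)

    for k, s in enumerate(starts):
        for side, pos in (("L", s - 1), ("R", s + R)):
            if not slot_ok(pos):
                continue
            forbidden: set[str] = set()
            for j, sj in enumerate(starts):
                if j == k:
                    continue
                same = orient[j] == orient[k]
                other_pos = (sj - 1 if side == "L" else sj + R) if same \
                    else (sj + R if side == "L" else sj - 1)
                if other_pos in chosen:
                    b = chosen[other_pos]
                    forbidden.add(b if same else _COMP[b])
            assign(pos, forbidden)


def _place(rng: np.random.Generator, L: int, R: int, n: int,
           occupied: list[tuple[int, int]], gap: int = 10,
           max_tries: int = 10000) -> list[int]:
    """Random non-overlapping placements, kept ``gap`` bp apart so
    planted copies never abut (tandem tests use explicit starts)."""
    placed = list(occupied)
    starts: list[int] = []
    for _ in range(max_tries):
        if len(starts) == n:
            break
        s = int(rng.integers(0, L - R + 1))
        if all(s + R + gap <= a or b + gap <= s for a, b in placed):
            placed.append((s, s + R))
            starts.append(s)
    if len(starts) < n:
        raise ValueError(f"could not place {n} copies of {R} bp in {L} bp")
    return starts


def make_fixture(length: int, specs: list[PlantSpec], seed: int = 0,
                 gc: float = 0.45, word_size: int = 50) -> tuple[GenomeSequence, TruthSet]:
    """Background plus several planted families, with a combined truth set.

    Placement is random non-overlapping across all families; explicit
    starts in a spec are honoured as given.
    """
    genome = generate_background(length, gc=gc, seed=seed, word_size=word_size)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    occupied: list[tuple[int, int]] = []
    truth = TruthSet()
    seq = genome.seq
    for j, spec in enumerate(specs):
        if spec.starts is None:
            starts = _place(rng, length, spec.length, spec.n_copies, occupied)
            spec = PlantSpec(spec.length, spec.n_copies, spec.orientations,
                             spec.mismatches, tuple(starts))
        occupied.extend((s, s + spec.length) for s in spec.starts)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        planted, t = plant_family(GenomeSequence(genome.id, seq), spec, seed=sub_seed)
        seq = planted.seq
        truth.families.extend(t.families)
    return GenomeSequence(id=genome.id, seq=seq), truth


# ---------------------------------------------------------------------------
# brute-force oracle


def _oracle_segments(m: np.ndarray, bar: np.ndarray, scoring: Scoring):
    """All X-drop-extended segments around maximal exact runs >= word_size
    of one (anti-)diagonal match vector. Yields (lo, hi, score, mm)."""
    w = scoring.word_size
    rew, pen = scoring.match_reward, scoring.mismatch_penalty
    xd = scoring.effective_xdrop
    n = len(m)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
    for r0, r1 in zip(edges[::2], edges[1::2]):
        if r1 - r0 < w:
            continue
        lo = _owalk(m, bar, int(r0) - 1, -1, 0, rew, pen, xd)
        hi = _owalk(m, bar, int(r1), +1, n - 1, rew, pen, xd) + 1
        mm = int(np.count_nonzero(~m[lo:hi]))
        score = rew * (hi - lo - mm) + pen * mm
        if score >= scoring.effective_min_score:
            yield lo, hi, score, mm


def _owalk(m, bar, start, step, stop, rew, pen, xd) -> int:
    delta = best = 0
    best_i = start - step
    i = start
    while (i <= stop) if step > 0 else (i >= stop):
        if bar[i]:
            break
        delta += rew if m[i] else pen
        if delta >= best:
            best, best_i = delta, i
        elif best - delta > xd:
            break
        i += step
    return best_i


def oracle_self_compare(genome: GenomeSequence,
                        scoring: Scoring | None = None) -> list[HSP]:
    """Exhaustive diagonal-scan self-comparison (reference implementation).

    Scans every plus-strand diagonal of genome x genome and every
    anti-diagonal of genome x reverse-complement, canonicalises
    identically to the engine, and never reports the full-length
    self-identity. Guarded to <= 20 kb (quadratic cost).
    """
    scoring = scoring or Scoring()
    L = len(genome)
    if L > 20000:
        raise ValueError(f"oracle guarded to <= 20 kb inputs, got {L}")
    codes = genome.codes()
    valid = codes != MASK_CODE
    w = scoring.word_size
    out: set[HSP] = set()

    # plus strand: diagonal offset d >= 1 (d = 0 is the self-identity)
    for d in range(1, L - w + 1):
        n = L - d
        ok = valid[:n] & valid[d:]
        m = (codes[:n] == codes[d:]) & ok
        for lo, hi, score, mm in _oracle_segments(m, ~ok, scoring):
            out.add(HSP(lo, hi, lo + d, hi + d, "+", score, mm))

    # minus strand: anti-diagonal c pairs position i with c - i
    for c in range(w - 1, 2 * L - w):
        i0, i1 = max(0, c - L + 1), min(L - 1, c)
        a = codes[i0:i1 + 1]
        b = codes[c - i1:c - i0 + 1][::-1]
        okv = valid[i0:i1 + 1] & valid[c - i1:c - i0 + 1][::-1]
        m = (a == 3 - b) & okv
        for lo, hi, score, mm in _oracle_segments(m, ~okv, scoring):
            q0, q1 = i0 + lo, i0 + hi
            s0, s1 = c - q1 + 1, c - q0 + 1
            if (s0, s1) < (q0, q1):
                q0, q1, s0, s1 = s0, s1, q0, q1
            out.add(HSP(q0, q1, s0, s1, "-", score, mm))

    return sorted(out, key=lambda h: (-h.score, h.q_start, h.q_end,
                                      h.s_start, h.s_end, h.strand))
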