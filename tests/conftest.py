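"""Shared fixtures and deterministic genome builders."""

from __future__ import annotations

import numpy as np
import pytest

from rouscan.seqio import GenomeSequence
from rouscan.synth import generate_background

_SWAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def mutate(base: str) -> str:
    """Deterministic substitution to a different base."""
    return _SWAP[base]


def planted_pair(unit: str, mut_offsets: tuple[int, ...] = (),
                 bg_len: int = 3000, c1: int = 200, c2: int = 1500,
                 seed: int = 9) -> GenomeSequence:
    """Two copies of ``unit`` planted at c1/c2 with substitutions in the
    second copy, and the diagonal positions just outside both copies
    forced to mismatch so alignments end exactly at the planted
    boundaries (random flanking matches would otherwise extend them)."""
    bg = generate_background(bg_len, seed=seed)
    s = bytearray(bg.seq, "ascii")
    R = len(unit)
    u2 = bytearray(unit, "ascii")
    for off in mut_offsets:
        u2[off] = ord(mutate(chr(u2[off])))
    s[c1:c1 + R] = unit.encode("ascii")
    s[c2:c2 + R] = bytes(u2)
    s[c1 - 1], s[c2 - 1] = ord("A"), ord("C")
    s[c1 + R], s[c2 + R] = ord("A"), ord("C")
    return GenomeSequence(id="pair", seq=s.decode("ascii"))


def random_unit(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def background_10k() -> GenomeSequence:
    return generate_background(10_000, gc=0.45, seed=123)
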