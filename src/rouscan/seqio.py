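"""Genome FASTA input, validation, and repeat-oriented output writers.

Coordinate convention: everything in memory is 0-based half-open; the
1-based inclusive GenBank/BLAST convention appears only in written files
(feature tables, TSV copy tables) and is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover
    from .curate import RepeatFamily

#: Sentinel residue for masked positions. It never matches anything,
#: including itself, and no alignment seed or extension may cross it.
MASK_CHAR = "N"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric residue codes used by the alignment engine: A,C,G,T -> 0..3 so
# that complement(x) == 3 - x; the mask sentinel gets the out-of-band 4.
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
_CODE_TABLE[ord(MASK_CHAR)] = 4
MASK_CODE = 4


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaError(ValueError):
    """Malformed or unusable genome FASTA input."""


class AmbiguityError(FastaError):
    """A residue outside {A,C,G,T} under the ``reject`` policy."""


@dataclass
class GenomeSequence:
    """A validated single nucleotide sequence.

    Attributes
    ----------
    id :
        Accession-like identifier taken from the FASTA header.
    seq :
        Uppercase residues over {A,C,G,T} plus the mask sentinel ``N``.
    circular :
        Whether the molecule should be treated as circular by the
        alignment engine (off by default).
    """

    id: str
    seq: str
    circular: bool = False
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def codes(self) -> np.ndarray:
        """uint8 encoding (A,C,G,T -> 0..3; mask -> 4), cached."""
        if self._codes is None or len(self._codes) != len(self.seq):
            self._codes = _CODE_TABLE[np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)]
        return self._codes

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(id=self.id, seq=reverse_complement(self.seq), circular=self.circular)


def validate_sequence(raw: str, ambiguity_policy: str = "reject") -> str:
    """Uppercase and validate a nucleotide string.

    Under ``reject`` any residue outside {A,C,G,T} raises
    :class:`AmbiguityError` naming the first offending (1-based) position.
    Under ``mask`` such residues are replaced by the mask sentinel.
    """
    if ambiguity_policy not in ("reject", "mask"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    seq = raw.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    good = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    if good.all():
        return seq
    if ambiguity_policy == "reject":
        pos = int(np.flatnonzero(~good)[0])
        raise AmbiguityError(
            f"non-ACGT residue {seq[pos]!r} at position {pos + 1}; "
            "use ambiguity_policy='mask' to mask it"
        )
    out = arr.copy()
    out[~good] = ord(MASK_CHAR)
    return out.tobytes().decode("ascii")


def read_fasta(path: str | Path, ambiguity_policy: str = "reject",
               circular: bool = False) -> GenomeSequence:
    """Read exactly one genome record from a FASTA file.

    Multi-record files are an error in single-genome mode (multi-chromosome
    genomes are out of scope; each molecule is analysed on its own).
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FastaError(
            f"{path}: {len(records)} records found; expected exactly one "
            "(multi-sequence input is not supported in single-genome mode)"
        )
    rec = records[0]
    if len(rec.seq) == 0:
        raise FastaError(f"{path}: record {rec.id!r} has zero-length sequence")
    seq = validate_sequence(str(rec.seq), ambiguity_policy)
    return GenomeSequence(id=rec.id, seq=seq, circular=circular)


def write_genome_fasta(genome: GenomeSequence, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.seq), id=genome.id, description="")],
                str(path), "fasta")


def sort_families(families: Iterable["RepeatFamily"]) -> list["RepeatFamily"]:
    """Deterministic family order: descending length, then ascending
    first-copy start, then lexicographic representative."""
    return sorted(
        families,
        key=lambda f: (-f.length, min(c.start for c in f.copies), f.representative),
    )


def write_repeat_fasta(families: Iterable["RepeatFamily"], path: str | Path) -> None:
    """One FASTA record per distinct repeat family.

    The header carries the family id, length and copy number
    (``R1 len=600 copies=2``); the sequence is the representative copy.
    An empty family list produces an empty file.
    """
    with open(path, "w") as fh:
        for fam in sort_families(families):
            fh.write(f">{fam.family_id} len={fam.length} copies={len(fam.copies)}\n")
            for i in range(0, fam.length, 70):
                fh.write(fam.representative[i:i + 70] + "\n")


def write_feature_table(families: Iterable["RepeatFamily"], genome_id: str,
                        path: str | Path, genome_length: int | None = None) -> None:
    """Write an NCBI 5-column feature table of ``repeat_region`` features.

    One feature per copy; minus-strand copies are encoded by start > end
    (1-based inclusive coordinates). Each feature carries the qualifiers
    ``rpt_type dispersed`` and ``note <family_id>``.
    """
    lines = [f">Feature {genome_id}"]
    for fam in sort_families(families):
        for copy in fam.copies:
            start1, end1 = copy.start + 1, copy.end  # 1-based inclusive
            if genome_length is not None and not (1 <= start1 <= end1 <= genome_length):
                raise ValueError(
                    f"copy {start1}..{end1} of {fam.family_id} outside genome "
                    f"of length {genome_length}"
                )
            a, b = (start1, end1) if copy.strand == "+" else (end1, start1)
            lines.append(f"{a}\t{b}\trepeat_region")
            lines.append("\t\t\trpt_type\tdispersed")
            lines.append(f"\t\t\tnote\t{fam.family_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Parse a feature table written by :func:`write_feature_table`.

    Returns the genome id and ``(family_id, start, end, strand)`` tuples
    with 0-based half-open coordinates.
    """
    genome_id = ""
    feats: list[tuple[str, int, int, str]] = []
    pending: tuple[int, int, str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">Feature"):
            genome_id = line.split(None, 1)[1].strip()
            continue
        cols = line.split("\t")
        if len(cols) >= 3 and cols[0] and cols[2] == "repeat_region":
            a, b = int(cols[0]), int(cols[1])
            if a <= b:
                pending = (a - 1, b, "+")
            else:
                pending = (b - 1, a, "-")
        elif len(cols) >= 5 and cols[3] == "note" and pending is not None:
            feats.append((cols[4], *pending))
            pending = None
    return genome_id, feats
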