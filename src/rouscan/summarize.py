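"""Per-genome repeat tables, size-binned spectra, batch runs, and the
group-fraction matrix across taxa.

The size spectrum is summarised by counting each repeat family once in
the bin containing its length. Across taxa the comparable statistic is,
per taxonomic group and size bin, the fraction of species in the group
with at least one repeat in that bin (species differ enormously in
total repeat count, so presence/absence per bin is what is compared).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curate import RepeatFamily, find_repeats
from .engine import Scoring
from .seqio import (GenomeSequence, read_fasta, sort_families,
                    write_feature_table, write_repeat_fasta)

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BIN_EDGES",
    "SizeBinTable",
    "GroupMatrix",
    "bin_repeats",
    "genome_repeat_table",
    "batch_run",
    "BatchResult",
    "group_fraction_matrix",
    "plot_group_matrix",
]

#: Default repeat-size bin edges (bp): 50, 100, 200 ... 900, 1000,
#: 2000 ... 10000; the last bin is unbounded. Spans the observed range
#: of dispersed repeats in plant mitochondria (~50 bp to >10 kb).
DEFAULT_BIN_EDGES: tuple[int, ...] = (50, 100, *range(200, 1000, 100),
                                      *range(1000, 10001, 1000))


def bin_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])]
    labels.append(f">={edges[-1]}")
    return labels


@dataclass
class SizeBinTable:
    """Binned repeat-family counts for one genome.

    Bins are right-open ``[a, b)`` except the last, which is unbounded;
    a repeat of exactly 200 bp falls in the bin starting at 200.
    """

    genome_id: str
    bin_edges: tuple[int, ...]
    counts: np.ndarray

    @property
    def labels(self) -> list[str]:
        return bin_labels(self.bin_edges)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.labels, name=self.genome_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.labels, "count": self.counts})


def _check_edges(bin_edges: Sequence[int]) -> tuple[int, ...]:
    edges = tuple(int(e) for e in bin_edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly increasing, got {edges}")
    return edges


def bin_repeats(families: Iterable[RepeatFamily],
                bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
                genome_id: str = "") -> SizeBinTable:
    """Count each family once in the unique bin containing its length.

    Families shorter than the first edge are not counted (they cannot
    arise with the default word size of 50 and first edge 50).
    """
    edges = _check_edges(bin_edges)
    counts = np.zeros(len(edges), dtype=int)
    for fam in families:
        k = int(np.searchsorted(edges, fam.length, side="right")) - 1
        if k >= 0:
            counts[k] += 1
    return SizeBinTable(genome_id=genome_id, bin_edges=edges, counts=counts)


def genome_repeat_table(families: Iterable[RepeatFamily],
                        genome_length: int | None = None,
                        genome_id: str = "") -> tuple[pd.DataFrame, dict]:
    """Per-copy table plus per-genome summary statistics.

    Copy coordinates are written 1-based inclusive. The summary reports
    the family count, the largest repeat length, the total repeated
    bases (sum over families of length x copy number) and, when the
    genome length is known, the fraction of the genome that is repeated.
    """
    fams = sort_families(families)
    rows = []
    for fam in fams:
        for k, c in enumerate(sorted(fam.copies, key=lambda c: c.start), start=1):
            rows.append({
                "family_id": fam.family_id,
                "length": fam.length,
                "copy_count": len(fam.copies),
                "copy_index": k,
                "start": c.start + 1,
                "end": c.end,
                "strand": c.strand,
                "mismatches": c.mismatches_vs_representative,
                "tandem_flag": fam.tandem_flag,
            })
    table = pd.DataFrame(rows, columns=["family_id", "length", "copy_count",
                                        "copy_index", "start", "end", "strand",
                                        "mismatches", "tandem_flag"])
    repeated_bp = int(sum(f.length * len(f.copies) for f in fams))
    summary = {
        "genome_id": genome_id,
        "n_families": len(fams),
        "largest_repeat_bp": max((f.length for f in fams), default=0),
        "total_repeated_bp": repeated_bp,
        "fraction_repeated": (repeated_bp / genome_length) if genome_length else 0.0,
    }
    return table, summary


@dataclass
class GenomeResult:
    genome: GenomeSequence
    families: list[RepeatFamily]
    table: pd.DataFrame
    summary: dict
    bins: SizeBinTable


@dataclass
class BatchResult:
    per_genome: dict[str, GenomeResult]
    combined: pd.DataFrame  # genomes x bins count matrix
    failures: dict[str, str]

    @property
    def ok(self) -> bool:
        return not self.failures


_FASTA_SUFFIXES = (".fa", ".fasta", ".fna")


def run_single(genome: GenomeSequence, scoring: Scoring | None = None,
               bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
               circular: bool | None = None,
               max_mismatch_rate: float = 0.01) -> GenomeResult:
    """Full discovery + summary pipeline for one genome."""
    scoring = scoring or Scoring()
    families = find_repeats(genome, scoring, circular=circular,
                            max_mismatch_rate=max_mismatch_rate)
    table, summary = genome_repeat_table(families, genome_length=len(genome),
                                         genome_id=genome.id)
    bins = bin_repeats(families, bin_edges, genome_id=genome.id)
    return GenomeResult(genome=genome, families=families, table=table,
                        summary=summary, bins=bins)


def write_genome_outputs(result: GenomeResult, out_dir: str | Path, stem: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_repeat_fasta(result.families, out_dir / f"{stem}_repeats.fasta")
    result.table.to_csv(out_dir / f"{stem}_copies.tsv", sep="\t", index=False)
    result.bins.to_frame().to_csv(out_dir / f"{stem}_bins.tsv", sep="\t", index=False)
    write_feature_table(result.families, result.genome.id,
                        out_dir / f"{stem}_features.tbl",
                        genome_length=len(result.genome))
    (out_dir / f"{stem}_summary.json").write_text(
        json.dumps(result.summary, indent=2) + "\n")


def batch_run(directory: str | Path, scoring: Scoring | None = None,
              out_dir: str | Path | None = None,
              bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
              ambiguity_policy: str = "reject",
              circular: bool = False,
              max_mismatch_rate: float = 0.01) -> BatchResult:
    """Run the full pipeline on every FASTA file in a directory.

    Files are processed in sorted filename order for reproducibility.
    A failure on one genome is logged and recorded without aborting the
    batch. The combined output is a genomes x size-bins count matrix.
    """
    scoring = scoring or Scoring()
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in _FASTA_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no FASTA files (*.fa, *.fasta, *.fna) in {directory}")

    per_genome: dict[str, GenomeResult] = {}
    failures: dict[str, str] = {}
    for path in files:
        stem = path.stem
        try:
            genome = read_fasta(path, ambiguity_policy, circular=circular)
            result = run_single(genome, scoring, bin_edges, circular=circular,
                                max_mismatch_rate=max_mismatch_rate)
        except Exception as exc:  # noqa: BLE001 - batch isolation by contract
            log.error("genome %s failed: %s", path.name, exc)
            failures[stem] = str(exc)
            continue
        per_genome[stem] = result
        if out_dir is not None:
            write_genome_outputs(result, Path(out_dir) / stem, stem)

    if not per_genome:
        raise RuntimeError(f"all {len(files)} genomes in {directory} failed")

    combined = pd.DataFrame(
        {stem: res.bins.to_series() for stem, res in per_genome.items()}
    ).T
    combined.index.name = "genome"
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        combined.to_csv(Path(out_dir) / "combined_bins.tsv", sep="\t")
    return BatchResult(per_genome=per_genome, combined=combined, failures=failures)


@dataclass
class GroupMatrix:
    """Per (taxon group, size bin): the fraction of species in the group
    with at least one repeat in that bin."""

    groups: list[str]
    bin_edges: tuple[int, ...]
    fractions: pd.DataFrame  # groups x bins, values in [0, 1]
    n_species: dict[str, int]


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (genome id/filename stem, group label), header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns with header")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def group_fraction_matrix(batch: BatchResult | pd.DataFrame,
                          group_map: dict[str, str],
                          bin_edges: Sequence[int] = DEFAULT_BIN_EDGES) -> GroupMatrix:
    """Fraction-of-species-with-a-repeat-per-bin matrix across groups.

    Every genome in the batch must appear in the group map; fractions
    are k/n with k the number of species in the group having >= 1
    family in the bin and n the group size.
    """
    edges = _check_edges(bin_edges)
    counts = batch.combined if isinstance(batch, BatchResult) else batch
    missing = [g for g in counts.index if g not in group_map]
    if missing:
        raise KeyError(f"genomes missing from group map: {', '.join(missing)}")
    presence = (counts > 0).astype(int)
    groups = presence.groupby([group_map[g] for g in counts.index])
    fractions = groups.mean()
    fractions.index.name = "group"
    n_species = {g: int(n) for g, n in groups.size().items()}
    return GroupMatrix(groups=list(fractions.index), bin_edges=edges,
                       fractions=fractions, n_species=n_species)


def plot_group_matrix(gm: GroupMatrix, path: str | Path) -> None:
    """Heat-map rendering of the group matrix (yellow=0 to blue=1)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("frac", ["#ffff66", "#2040c0"])
    fig, ax = plt.subplots(
        figsize=(0.5 * gm.fractions.shape[1] + 2, 0.4 * gm.fractions.shape[0] + 2))
    im = ax.imshow(gm.fractions.to_numpy(), cmap=cmap, vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(gm.fractions.shape[1]), gm.fractions.columns,
                  rotation=90, fontsize=7)
    ax.set_yticks(range(gm.fractions.shape[0]),
                  [f"{g} (n={gm.n_species[g]})" for g in gm.fractions.index],
                  fontsize=8)
    fig.colorbar(im, ax=ax, label="fraction of species with >=1 repeat")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
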