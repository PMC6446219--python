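"""Core domain types shared by all stages.

Coordinates are 0-based half-open throughout; GTF I/O converts at the
boundary.  Reads carry decoded phred scores (offset already removed), so a
read is encoding-agnostic once parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


class Mate(str, Enum):
    SINGLE = "single"
    MATE1 = "mate1"
    MATE2 = "mate2"


@dataclass(frozen=True)
class SequenceRead:
    """A sequencing read with per-base phred quality scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    mate: Mate = Mate.SINGLE

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.quals and (min(self.quals) < 0 or max(self.quals) > 93):
            raise ValueError(
                f"read {self.read_id!r}: phred scores outside [0, 93]; "
                "wrong quality encoding offset?"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class TranscriptModel:
    """A transcript: ordered exon intervals on its parent gene's chromosome."""

    tx_id: str
    parent_gene: str
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"transcript {self.tx_id}: empty exon [{s}, {e})")
        if not self.exons:
            raise ValueError(f"transcript {self.tx_id}: no exons")


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class Reference:
    """Toy reference: genome sequences plus gene/transcript models."""

    genome: dict[str, str]
    genes: list[GeneModel]

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes for t in g.transcripts]

    def transcript_sequence(self, tx: TranscriptModel) -> str:
        """Spliced transcript sequence, reverse-complemented for '-' genes."""
        gene = self.gene_by_id(tx.parent_gene)
        chrom = self.genome[gene.chrom]
        seq = "".join(chrom[s:e] for s, e in sorted(tx.exons))
        return revcomp(seq) if gene.strand == "-" else seq

    def contains(self, query: str) -> bool:
        """Exact substring search on either strand of any chromosome."""
        rc = revcomp(query)
        return any(query in seq or rc in seq for seq in self.genome.values())
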