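"""Core genomic domain types.

All coordinates are 0-based half-open (BED convention) throughout the
package; the GTF reader converts its 1-based inclusive coordinates on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open coordinate span [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeSpec:
    """Ordered chromosomes with lengths and X/autosome stratum labels."""

    chroms: list[tuple[str, int, str]]  # (name, length, stratum)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in GenomeSpec")
        for name, length, stratum in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if stratum not in ("X", "autosome"):
                raise ValueError(f"unknown stratum {stratum!r} for {name}")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chroms]

    def length(self, chrom: str) -> int:
        for name, length, _ in self.chroms:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def stratum(self, chrom: str) -> str:
        for name, _, stratum in self.chroms:
            if name == chrom:
                return stratum
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    @property
    def total_length(self) -> int:
        return sum(c[1] for c in self.chroms)


@dataclass
class GeneModel:
    """A gene as a set of exons; tss follows the strand convention.

    tss = span.start on + strand, span.end - 1 on - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = exons

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end,
            name=self.gene_id, strand=self.strand,
        )

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def exonic_length(self) -> int:
        """Union-of-exons length in bp (exons are stored non-overlapping)."""
        return sum(e.length for e in self.exons)
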