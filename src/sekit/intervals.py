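"""Core genomic value types.

Every coordinate in the package is 0-based, half-open (BED convention).
One-based formats convert at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Length in bp of the intersection with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0


@dataclass(frozen=True)
class Peak:
    """A MACS-style enhancer call; ``pileup`` is the signal height."""

    interval: GenomicInterval
    pileup: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.pileup < 0:
            raise ValueError(f"pileup must be non-negative, got {self.pileup}")


@dataclass(frozen=True)
class Read:
    """One aligned read, reduced to its genomic footprint."""

    interval: GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-resolved transcription start site.

    ``tss`` is the 0-based coordinate of the 5' end: ``span.start`` on the
    plus strand, ``span.end - 1`` on the minus strand.
    """

    name: str
    strand: str
    tss: int
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.span.start <= self.tss < self.span.end):
            raise ValueError("tss must lie within the gene span")

    @property
    def chrom(self) -> str:
        return self.span.chrom


@dataclass
class StitchedEnhancer:
    """A stitched run of peaks with its score, rank and SE/TE flag.

    ``count`` is the cumulative read-base signal over the region support;
    ``rank`` is 1 for the highest count. Both are filled by the calling
    pipeline; freshly stitched regions carry ``count=0.0, rank=0``.
    """

    interval: GenomicInterval
    subpeaks: list[Peak] = field(default_factory=list)
    count: float = 0.0
    rank: int = 0
    is_se: bool = False

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def n_subpeaks(self) -> int:
        return len(self.subpeaks)
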