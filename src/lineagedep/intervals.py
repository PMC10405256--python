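"""Genomic interval primitives.

All coordinates are 0-based half-open, the native convention of BED and
narrowPeak, so widths are always ``end - start`` and no shift is applied
on I/O. Strand is carried but ignored by overlap logic except where reads
are extended from their 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return self.start + self.width // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share at least one base (strand-blind)."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies entirely within this interval."""
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass(frozen=True, slots=True)
class Peak:
    """A called accessibility peak with its summit and significance.

    ``summit`` is the absolute base position of maximal signal;
    ``neg_log10_q`` is the MACS2-style -log10(q) significance. The extra
    narrowPeak columns (score, signal, -log10 p) are carried so files
    round-trip.
    """

    interval: GenomicInterval
    summit: int
    neg_log10_q: float
    name: str
    score: int = 0
    signal: float = 0.0
    neg_log10_p: float = -1.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.neg_log10_q < 0:
            raise ValueError(f"neg_log10_q must be >= 0, got {self.neg_log10_q}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True, slots=True)
class ConsensusPeak:
    """Fixed-width, summit-centered representative peak.

    Chosen by significance-ranked greedy selection so that no two consensus
    peaks overlap; ``source_peak`` names the winning input peak.
    """

    interval: GenomicInterval
    summit: int
    source_peak: str
    neg_log10_q: float

    @property
    def chrom(self) -> str:
        return self.interval.chrom


DE_STATUSES = ("up", "down", "unchanged", "not_expressed")


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene anchored at its TSS with its differential-expression label."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "."
    de_status: str = "unchanged"
    log2fc: float | None = None
    padj: float | None = None

    def __post_init__(self) -> None:
        if self.de_status not in DE_STATUSES:
            raise ValueError(f"de_status must be one of {DE_STATUSES}, got {self.de_status!r}")
        if self.de_status == "up" and self.log2fc is not None and self.log2fc <= 0:
            raise ValueError("de_status 'up' requires log2fc > 0")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must be in [0,1], got {self.padj}")
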