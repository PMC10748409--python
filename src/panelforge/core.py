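"""Core genomic value types shared across the pipeline.

Coordinate convention: intervals are 0-based, half-open internally;
every user-facing table is 1-based. The two conversion helpers below are
the only place the convention is switched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def distance_to_point(self, pos0: int) -> int:
        """Distance from a 0-based position to the interval (0 if inside)."""
        if pos0 < self.start:
            return self.start - pos0
        if pos0 >= self.end:
            return pos0 - self.end + 1
        return 0

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def to_one_based(start0: int) -> int:
    """0-based start -> 1-based position."""
    return start0 + 1


def to_zero_based(pos1: int) -> int:
    """1-based position -> 0-based start."""
    return pos1 - 1


@dataclass(frozen=True)
class SnpRecord:
    """A curated disease-associated SNP in the source species.

    ``ref_allele``/``alt_allele`` may be empty strings for literature
    entries that report only an rsID; ``association_p`` is None when the
    source does not report one (e.g. manually curated catalogs).
    """

    rsid: str
    chrom: str = ""
    pos: int = 0  # 1-based; 0 means unknown
    ref_allele: str = ""
    alt_allele: str = ""
    sources: frozenset = field(default_factory=frozenset)
    species: str = ""
    association_p: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 0:
            raise ValueError("pos must be >= 1 (or 0 for unknown)")
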