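"""Core genomic record types shared across the package.

All in-memory coordinates are 0-based, half-open (BED convention). The
extended pairs dialect on disk is 1-based (pairs ecosystem convention);
conversion happens in :mod:`factorfinder.readwrite` and nowhere else.

A censored fragment length (fragment longer than what an observed ligation
can reveal) is represented as ``frag_len = None``, never as a negative
number, so it cannot silently leak into arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "Motif",
    "SignalPeak",
    "ContactSide",
    "Contact",
    "STRANDS",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based start (inclusive) and end (exclusive); ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Motif:
    """A CTCF binding-site motif instance (CBS). Strand is required.

    ``center`` is the floor of the interval midpoint, so it is deterministic
    for even-length motifs.
    """

    interval: GenomicInterval
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("motif strand must be '+' or '-'")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class SignalPeak:
    """A ChIP-seq peak interval carrying a signal value (narrowPeak-like)."""

    interval: GenomicInterval
    signal_value: float = 0.0
    summit_offset: Optional[int] = None
    name: str = "."

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.signal_value):
            raise ValueError("signal_value must be finite")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit(self) -> int:
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class ContactSide:
    """One side of a proximity-ligation contact.

    ``pos5`` is the 0-based 5' end of the sequenced read.  ``frag_len`` is
    the pre-ligation fragment length in bp when the ligation junction was
    observed within the read, and ``None`` (censored) otherwise.
    """

    chrom: str
    pos5: int
    strand: str
    frag_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"side strand must be '+' or '-', got {self.strand!r}")
        if self.pos5 < 0:
            raise ValueError(f"pos5 must be >= 0, got {self.pos5}")
        if self.frag_len is not None and self.frag_len < 1:
            raise ValueError(f"known frag_len must be >= 1, got {self.frag_len}")

    @property
    def observed_ligation(self) -> bool:
        return self.frag_len is not None

    @property
    def is_censored(self) -> bool:
        return self.frag_len is None


@dataclass(frozen=True)
class Contact:
    """A single proximity-ligation event (one single-cell contact).

    Sides are ordered by ``(chrom, pos5)`` at construction so that
    ``side1 <= side2``; analyses can rely on this invariant.
    """

    side1: ContactSide = field()
    side2: ContactSide = field()

    def __post_init__(self) -> None:
        a, b = self.side1, self.side2
        if (b.chrom, b.pos5) < (a.chrom, a.pos5):
            object.__setattr__(self, "side1", b)
            object.__setattr__(self, "side2", a)

    @property
    def is_cis(self) -> bool:
        return self.side1.chrom == self.side2.chrom

    def sides(self) -> tuple:
        return (self.side1, self.side2)
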