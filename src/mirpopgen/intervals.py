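"""Genomic interval arithmetic.

All internal coordinates are half-open, 0-based.  User-facing formats
(GFF3, VCF, report tables) are 1-based inclusive; the two conversion
helpers below are the only place the convention changes hands.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open 0-based interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start in interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersection(self, other: "Interval") -> "Interval | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Interval(lo, hi) if lo < hi else None

    def to_1based(self) -> tuple[int, int]:
        """Return (start, end) as 1-based inclusive coordinates."""
        return self.start + 1, self.end

    @classmethod
    def from_1based(cls, start: int, end: int) -> "Interval":
        """Build from 1-based inclusive coordinates."""
        return cls(start - 1, end)
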