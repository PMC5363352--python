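"""Genomic intervals in 1-based inclusive coordinates.

All public coordinates in this package are 1-based inclusive (the convention
used for HGVS-style breakpoint reporting). BED serialization converts to the
0-based half-open file convention in :mod:`segdupcnv.io`; that converter is
the single place where the two conventions meet.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval ``[start, end]`` on a sequence, 1-based."""

    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} greater than end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint)."""
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)


def interval_length(interval: GenomicInterval | tuple[int, int]) -> int:
    """Length in bp of a 1-based inclusive interval: ``end - start + 1``.

    Accepts a :class:`GenomicInterval` or a bare ``(start, end)`` pair, so
    printed coordinates can be measured directly::

        >>> interval_length((159806619, 159815757))
        9139
    """
    if isinstance(interval, GenomicInterval):
        return len(interval)
    start, end = interval
    if start > end:
        raise ValueError(f"interval start {start} greater than end {end}")
    return end - start + 1
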