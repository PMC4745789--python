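"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``
(BED convention). Any 1-based input format is converted at the reader
boundary, never downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

#: Sentinel distance between intervals on different chromosomes.
INF_DISTANCE = math.inf

_VALID_STRANDS = {"+", "-", "."}


def _normalize_strand(strand: str) -> str:
    # tolerate the typographic minus that shows up in hand-written tables
    if strand in ("−", "–"):
        return "-"
    return strand


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located genomic feature: ``chrom:[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", _normalize_strand(self.strand))
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # used as a stable feature id
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq peak: an interval plus a score and optional summit."""

    interval: GenomicInterval
    score: float = 0.0
    summit_offset: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError("summit_offset must lie within the peak")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS and an expression level (FPKM-like units)."""

    gene_id: str
    tss: GenomicInterval
    expression: float = 0.0

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.tss.length != 1:
            raise ValueError("tss must be a length-1 interval")
        if self.expression < 0:
            raise ValueError("expression must be nonnegative")

    @property
    def tss_position(self) -> int:
        return self.tss.start


def interval_relate(a: GenomicInterval, b: GenomicInterval) -> dict:
    """Overlap length and gap distance between two intervals.

    Returns ``{"overlap": int, "distance": number}`` where overlap is
    ``max(0, min(end) - max(start))`` and distance is 0 when the intervals
    overlap or abut, else the size of the gap between them. Intervals on
    different chromosomes have overlap 0 and infinite distance.
    The relation is symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return {"overlap": 0, "distance": INF_DISTANCE}
    overlap = max(0, min(a.end, b.end) - max(a.start, b.start))
    if overlap > 0:
        distance = 0
    else:
        distance = max(a.start, b.start) - min(a.end, b.end)
    return {"overlap": overlap, "distance": distance}


def sort_key(interval: GenomicInterval):
    return (interval.chrom, interval.start, interval.end)
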