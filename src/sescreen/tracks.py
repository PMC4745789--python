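"""Piecewise-constant signal tracks in reads-per-million density units.

A :class:`SignalTrack` maps base position to RPM-per-base density; it is
zero wherever no segment covers a position. Tracks arriving through
:func:`sescreen.io.read_bedgraph` are assumed pre-normalized to RPM — the
pipeline never sees raw read counts.
"""
from __future__ import annotations

import logging
from typing import Dict, Iterable, Tuple

import numpy as np

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class SignalTrack:
    """Per-chromosome sorted non-overlapping segments with float values."""

    def __init__(self, segments: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # segments: chrom -> (starts, ends, values), validated here once
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged segment arrays")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal values")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted segment")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"{chrom}: overlapping segments "
                    f"[{starts[i]},{ends[i]}) and [{starts[i+1]},{ends[i+1]})"
                )
            self._data[chrom] = (starts, ends, values)
        self._warned_chroms: set = set()

    @classmethod
    def from_segments(
        cls, records: Iterable[Tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: Dict[str, list] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        segs = {}
        for chrom, rows in by_chrom.items():
            arr = np.array(rows, dtype=np.float64).reshape(-1, 3)
            segs[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(segs)

    @classmethod
    def empty(cls) -> "SignalTrack":
        return cls({})

    @property
    def chroms(self):
        return list(self._data)

    def segments(self, chrom: str):
        return self._data.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def iter_segments(self):
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def value_at(self, chrom: str, position: int) -> float:
        starts, ends, values = self.segments(chrom)
        if len(starts) == 0:
            return 0.0
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < ends[i]:
            return float(values[i])
        return 0.0

    def region_signal(self, region: GenomicInterval) -> float:
        """Integral of density over the region (RPM): Σ value × overlap length."""
        if region.chrom not in self._data:
            if region.chrom not in self._warned_chroms:
                logger.warning(
                    "chromosome %s absent from track; returning 0 signal",
                    region.chrom,
                )
                self._warned_chroms.add(region.chrom)
            return 0.0
        starts, ends, values = self._data[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], region.end) - np.maximum(starts[lo:hi], region.start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov.astype(np.float64), values[lo:hi]))

    def scaled(self, factor: float) -> "SignalTrack":
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return SignalTrack(
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._data.items()}
        )


def region_signal(track: SignalTrack, region: GenomicInterval) -> float:
    """Module-level alias for :meth:`SignalTrack.region_signal`."""
    return track.region_signal(region)
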