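"""Metagene profiles: average signal over scaled region bodies plus flanks.

Each region's body is rescaled to a fixed number of bins and fixed-width
flanks are added on both sides, so regions of very different lengths
(~2 kb typical enhancers vs ~30 kb super-enhancers) can be averaged and
compared side by side. Bin values are densities (RPM per base), not raw
sums, so profile height does not trivially scale with region length.
Enhancers are unstranded, so no orientation flipping is applied.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .intervals import GenomicInterval
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

DEFAULT_BODY_BINS = 50
DEFAULT_FLANK_BP = 5_000
DEFAULT_FLANK_BINS = 25


@dataclass(frozen=True)
class MetageneProfile:
    body_bins: int
    flank_bp: int
    flank_bins: int
    mean_signal: np.ndarray  # length flank_bins + body_bins + flank_bins
    n_regions: int
    n_skipped: int = 0
    median_region_length: float = float("nan")

    def __post_init__(self) -> None:
        expected = self.flank_bins + self.body_bins + self.flank_bins
        if len(self.mean_signal) != expected:
            raise ValueError("mean_signal length mismatch")
        if self.n_regions < 1:
            raise ValueError("profile needs at least one region")


def _bin_edges(lo: int, hi: int, n_bins: int) -> np.ndarray:
    """Integer bin edges splitting [lo, hi) proportionally into n_bins."""
    length = hi - lo
    return lo + (np.arange(n_bins + 1) * length) // n_bins


def region_profile(
    region: GenomicInterval,
    track: SignalTrack,
    body_bins: int,
    flank_bp: int,
    flank_bins: int,
) -> np.ndarray:
    """Per-bin density vector for one region (flank | body | flank)."""
    edges: List[int] = []
    if flank_bp > 0:
        edges.extend(_bin_edges(region.start - flank_bp, region.start, flank_bins)[:-1])
    else:
        edges.extend([region.start] * flank_bins)
    edges.extend(_bin_edges(region.start, region.end, body_bins)[:-1])
    if flank_bp > 0:
        edges.extend(_bin_edges(region.end, region.end + flank_bp, flank_bins))
    else:
        edges.extend([region.end] * (flank_bins + 1))

    values = np.zeros(len(edges) - 1)
    for i in range(len(edges) - 1):
        a, b = int(edges[i]), int(edges[i + 1])
        width = b - a
        if width <= 0:
            values[i] = 0.0
            continue
        # clip at chromosome start; the uncovered prefix contributes zero
        qa, qb = max(0, a), max(0, b)
        signal = track.region_signal(GenomicInterval(region.chrom, qa, qb)) if qb > qa else 0.0
        values[i] = signal / width
    return values


def build_metagene(
    regions: Sequence[GenomicInterval],
    track: SignalTrack,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bp: int = DEFAULT_FLANK_BP,
    flank_bins: int = DEFAULT_FLANK_BINS,
) -> MetageneProfile:
    """Average per-bin density across regions.

    Regions shorter than ``body_bins`` bases are skipped (with a warning)
    and tallied in ``n_skipped``. Flanks clipped at a chromosome start are
    zero-padded.
    """
    if body_bins < 1 or flank_bins < 1:
        raise ValueError("body_bins and flank_bins must be >= 1")
    if flank_bp < 0:
        raise ValueError("flank_bp must be nonnegative")
    if 0 < flank_bp < flank_bins:
        raise ValueError("flank_bp must be 0 or >= flank_bins")
    if not regions:
        raise ValueError("regions must be non-empty")

    profiles = []
    lengths = []
    n_skipped = 0
    for region in regions:
        if region.length < body_bins:
            logger.warning("region %s shorter than body_bins; skipped", region)
            n_skipped += 1
            continue
        profiles.append(region_profile(region, track, body_bins, flank_bp, flank_bins))
        lengths.append(region.length)
    if not profiles:
        raise ValueError("all regions were shorter than body_bins")
    return MetageneProfile(
        body_bins=body_bins,
        flank_bp=flank_bp,
        flank_bins=flank_bins,
        mean_signal=np.mean(profiles, axis=0),
        n_regions=len(profiles),
        n_skipped=n_skipped,
        median_region_length=float(np.median(lengths)),
    )
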