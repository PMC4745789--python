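"""Enhancer definition, stitching, ranking and super-enhancer calling.

The workflow mirrors the standard H3K27Ac super-enhancer recipe: H3K27Ac
peaks away from transcription start sites and free of H3K4me3 define
enhancer candidates; nearby candidates are stitched into enhancers;
enhancers are ranked by total H3K27Ac signal; and the characteristic
hockey-stick rank/signal curve is cut to separate super-enhancers (the
high-signal suffix) from typical enhancers.

Defaults follow the ROSE conventions: 2,500 bp TSS exclusion and
12,500 bp stitching. The ROSE refinement that suspends stitching across
regions spanning three or more TSSs is deliberately not implemented.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, GeneModel, Peak, sort_key
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

DEFAULT_TSS_EXCLUSION_BP = 2500
DEFAULT_STITCH_DISTANCE_BP = 12500
DEFAULT_K4ME3_OVERLAP_FRACTION = 0.5


class EnhancerClass(str, Enum):
    TYPICAL = "TYPICAL"
    SUPER = "SUPER"


@dataclass
class Enhancer:
    """A stitched enhancer: hull region, constituent peaks, and its rank."""

    region: GenomicInterval
    constituents: List[Peak]
    signal: Optional[float] = None
    rank: Optional[int] = None
    klass: Optional[EnhancerClass] = None

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("enhancer must have at least one constituent")
        for peak in self.constituents:
            if (
                peak.chrom != self.region.chrom
                or peak.start < self.region.start
                or peak.end > self.region.end
            ):
                raise ValueError("region must span all constituents")
        if self.signal is not None and self.signal < 0:
            raise ValueError("signal must be nonnegative")

    @property
    def eid(self) -> str:
        return str(self.region)

    @property
    def length(self) -> int:
        return self.region.length


@dataclass
class EnhancerRanking:
    """Enhancers sorted by ascending signal plus the super/typical cutoff."""

    enhancers: List[Enhancer]
    total_signal: float
    cutoff_index: Optional[int] = None
    cutoff_signal: Optional[float] = None
    method: Optional[str] = None

    def __post_init__(self) -> None:
        signals = self.signals
        if np.any(np.diff(signals) < 0):
            raise ValueError("enhancers must be sorted by ascending signal")

    @property
    def signals(self) -> np.ndarray:
        return np.array([e.signal for e in self.enhancers], dtype=float)

    @property
    def super_enhancers(self) -> List[Enhancer]:
        return [e for e in self.enhancers if e.klass is EnhancerClass.SUPER]

    @property
    def typical_enhancers(self) -> List[Enhancer]:
        return [e for e in self.enhancers if e.klass is EnhancerClass.TYPICAL]

    def signal_of(self, eid: str) -> float:
        for e in self.enhancers:
            if e.eid == eid:
                return e.signal
        raise KeyError(eid)


def define_candidates(
    k27ac_peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    k4me3_peaks: Sequence[Peak],
    tss_exclusion_bp: int = DEFAULT_TSS_EXCLUSION_BP,
    k4me3_overlap_fraction: float = DEFAULT_K4ME3_OVERLAP_FRACTION,
) -> List[Peak]:
    """Filter H3K27Ac peaks to distal, promoter-mark-free enhancer candidates.

    A peak survives iff its midpoint lies more than ``tss_exclusion_bp``
    from every TSS and its maximal single-peak overlap with H3K4me3 is
    below ``k4me3_overlap_fraction`` of its own length. Midpoint distance
    (rather than any-overlap) keeps the decision stable when broad peak
    shoulders graze a TSS window.
    """
    if tss_exclusion_bp < 0:
        raise ValueError("tss_exclusion_bp must be nonnegative")
    if not (0.0 <= k4me3_overlap_fraction <= 1.0):
        raise ValueError("k4me3_overlap_fraction must lie in [0, 1]")

    tss_by_chrom: Dict[str, List[int]] = {}
    for gene in gene_models:
        tss_by_chrom.setdefault(gene.tss.chrom, []).append(gene.tss_position)
    for positions in tss_by_chrom.values():
        positions.sort()

    k4_by_chrom: Dict[str, tuple] = {}
    for chrom in {p.chrom for p in k4me3_peaks}:
        rows = sorted((p.start, p.end) for p in k4me3_peaks if p.chrom == chrom)
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        cummax_end = np.maximum.accumulate(ends)
        k4_by_chrom[chrom] = (starts, ends, cummax_end)

    kept: List[Peak] = []
    for peak in k27ac_peaks:
        mid = peak.interval.midpoint
        positions = tss_by_chrom.get(peak.chrom)
        if positions:
            i = bisect.bisect_left(positions, mid)
            near = min(
                (abs(mid - positions[j]) for j in (i - 1, i) if 0 <= j < len(positions)),
                default=None,
            )
            if near is not None and near <= tss_exclusion_bp:
                continue
        entry = k4_by_chrom.get(peak.chrom)
        if entry is not None:
            starts, ends, cummax_end = entry
            hi = int(np.searchsorted(starts, peak.end, side="left"))
            lo = int(np.searchsorted(cummax_end, peak.start, side="right"))
            max_overlap = 0
            for j in range(lo, hi):
                ov = min(ends[j], peak.end) - max(starts[j], peak.start)
                if ov > max_overlap:
                    max_overlap = int(ov)
            if max_overlap >= k4me3_overlap_fraction * peak.interval.length:
                continue
        kept.append(peak)
    return kept


def stitch(peaks: Sequence[Peak], stitch_distance_bp: int = DEFAULT_STITCH_DISTANCE_BP) -> List[Enhancer]:
    """Merge peaks whose gap is at most ``stitch_distance_bp`` (transitively).

    The resulting enhancers are disjoint hulls separated by more than the
    stitch distance; stitching is idempotent.
    """
    if stitch_distance_bp < 0:
        raise ValueError("stitch_distance_bp must be nonnegative")
    ordered = sorted(peaks, key=lambda p: sort_key(p.interval))
    enhancers: List[Enhancer] = []
    group: List[Peak] = []
    for peak in ordered:
        if group and peak.chrom == group[-1].chrom:
            cur_end = max(p.end for p in group)
            gap = peak.start - cur_end
            if gap <= stitch_distance_bp:
                group.append(peak)
                continue
        if group:
            enhancers.append(_hull(group))
        group = [peak]
    if group:
        enhancers.append(_hull(group))
    return enhancers


def _hull(group: List[Peak]) -> Enhancer:
    region = GenomicInterval(
        group[0].chrom, min(p.start for p in group), max(p.end for p in group)
    )
    return Enhancer(region=region, constituents=list(group))


def quantify_and_rank(
    enhancers: Sequence[Enhancer],
    k27ac_track: SignalTrack,
    control_track: Optional[SignalTrack] = None,
) -> EnhancerRanking:
    """Quantify enhancer H3K27Ac signal (RPM) and sort ascending.

    With a control track, the control signal is subtracted and the result
    floored at zero. Ties are broken by genomic position so ranks are
    reproducible.
    """
    quantified = []
    for enh in enhancers:
        signal = k27ac_track.region_signal(enh.region)
        if control_track is not None:
            signal = max(0.0, signal - control_track.region_signal(enh.region))
        quantified.append(replace(enh, signal=signal, rank=None, klass=None))
    quantified.sort(key=lambda e: (e.signal, sort_key(e.region)))
    for i, enh in enumerate(quantified):
        enh.rank = i + 1
    return EnhancerRanking(
        enhancers=quantified,
        total_signal=float(sum(e.signal for e in quantified)),
    )


def call_super(
    ranking: EnhancerRanking,
    method: str = "tangent",
    n: Optional[int] = None,
) -> EnhancerRanking:
    """Assign SUPER/TYPICAL classes and set the ranking cutoff.

    tangent
        Scale ascending rank index to x in [0,1] and signal to y in [0,1]
        (divide by the maximum); the cutoff index minimizes y - x (the
        point where the hockey-stick curve pulls away from the diagonal).
        SUPER means signal strictly above the cutoff signal.
    top_n
        The ``n`` highest-signal enhancers are SUPER.
    half_signal
        The smallest top-signal set whose summed signal first exceeds half
        of the total is SUPER.

    In every method the SUPER set is a suffix of the ascending ranking.
    """
    if not ranking.enhancers:
        raise ValueError("ranking is empty")
    signals = ranking.signals
    count = len(signals)

    if method == "tangent":
        if count < 2:
            raise ValueError("tangent method needs at least two enhancers")
        smax = signals[-1]
        if smax <= 0:
            raise ValueError("tangent method needs positive signal")
        x = np.arange(count) / (count - 1)
        y = signals / smax
        cutoff_signal = float(signals[int(np.argmin(y - x))])
        # keep index consistent with the strict-inequality class rule
        cutoff_index = int(np.searchsorted(signals, cutoff_signal, side="right")) - 1
    elif method == "top_n":
        if n is None:
            raise ValueError("top_n method requires n")
        if n <= 0 or n > count:
            raise ValueError(f"n must lie in [1, {count}]")
        cutoff_index = count - n - 1
        cutoff_signal = float(signals[cutoff_index]) if cutoff_index >= 0 else 0.0
    elif method == "half_signal":
        total = float(signals.sum())
        cum = 0.0
        k = 0
        for s in signals[::-1]:
            cum += s
            k += 1
            if cum > total / 2:
                break
        cutoff_index = count - k - 1
        cutoff_signal = float(signals[cutoff_index]) if cutoff_index >= 0 else 0.0
    else:
        raise ValueError(f"unknown method {method!r}")

    enhancers = [
        replace(
            e,
            klass=EnhancerClass.SUPER if i > cutoff_index else EnhancerClass.TYPICAL,
        )
        for i, e in enumerate(ranking.enhancers)
    ]
    for i, e in enumerate(enhancers):
        e.rank = i + 1
    return EnhancerRanking(
        enhancers=enhancers,
        total_signal=ranking.total_signal,
        cutoff_index=cutoff_index,
        cutoff_signal=cutoff_signal,
        method=method,
    )


def top_k_signal_fraction(ranking: EnhancerRanking, k: int) -> float:
    """Fraction of total signal carried by the k highest-signal enhancers."""
    count = len(ranking.enhancers)
    if not (1 <= k <= count):
        raise ValueError(f"k must lie in [1, {count}]")
    signals = ranking.signals
    total = float(signals.sum())
    if total == 0:
        return 0.0
    return float(signals[count - k :].sum() / total)


def summarize_ranking(ranking: EnhancerRanking) -> dict:
    """Headline numbers: counts, SUPER signal share, median lengths."""
    if any(e.klass is None for e in ranking.enhancers):
        raise ValueError("call_super must be applied before summarizing")
    supers = ranking.super_enhancers
    typicals = ranking.typical_enhancers
    summary = {
        "n_enhancers": len(ranking.enhancers),
        "n_super": len(supers),
        "n_typical": len(typicals),
        "total_signal": ranking.total_signal,
        "super_signal_fraction": (
            top_k_signal_fraction(ranking, len(supers)) if supers else 0.0
        ),
        "median_length_typical": (
            float(np.median([e.length for e in typicals])) if typicals else float("nan")
        ),
        "median_length_super": (
            float(np.median([e.length for e in supers])) if supers else float("nan")
        ),
        "method": ranking.method,
        "cutoff_signal": ranking.cutoff_signal,
    }
    return summary
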