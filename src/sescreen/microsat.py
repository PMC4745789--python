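"""GGAA microsatellite scanning and region enrichment statistics.

The EWS/FLI1 fusion binds tandem GGAA repeats, so super-enhancers in
Ewing sarcoma are expected to be enriched both for EWS/FLI1 ChIP peaks
and for GGAA microsatellites, and microsatellites under EWS/FLI1 peaks
are expected to carry more repeat units. This module finds maximal exact
tandem runs of a 4-mer unit (both orientations) and provides the
region-overlap Fisher enrichment and the repeat-count comparison.

Only exact, uninterrupted repeats are reported; runs are broken by any
mismatching base, including N.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, Peak
from .stats import (
    ContingencyTable2x2,
    EnrichmentResult,
    fisher_exact,
    welch_t_test,
)
from .io import as_sequence_source

DEFAULT_UNIT = "GGAA"
DEFAULT_MIN_REPEATS = 2

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Microsatellite:
    """A maximal tandem run: ``unit`` repeated ``repeat_count`` times."""

    region: GenomicInterval
    unit: str
    repeat_count: int

    def __post_init__(self) -> None:
        if self.region.length != len(self.unit) * self.repeat_count:
            raise ValueError("length must equal unit length x repeat_count")


def scan_microsatellites(
    sequence_source,
    unit: str = DEFAULT_UNIT,
    min_repeats: int = DEFAULT_MIN_REPEATS,
) -> List[Microsatellite]:
    """All maximal runs of >= ``min_repeats`` tandem copies of ``unit``.

    Scans the forward strand for ``unit`` and for its reverse complement
    (reported with the reverse-complement unit, e.g. TTCC for GGAA),
    case-insensitively. Maximality means neither end can be extended by
    one more unit copy.
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    unit = unit.upper()
    if len(unit) != 4 or any(b not in "ACGT" for b in unit):
        raise ValueError("unit must be a 4-mer over ACGT")
    source = as_sequence_source(sequence_source)
    units = [unit]
    rc = reverse_complement(unit)
    if rc != unit:
        units.append(rc)

    found: List[Microsatellite] = []
    for chrom in source.chroms():
        seq = source.sequence(chrom).upper()
        for u in units:
            pattern = re.compile(f"(?:{u}){{{min_repeats},}}")
            for match in pattern.finditer(seq):
                start, end = match.span()
                found.append(
                    Microsatellite(
                        region=GenomicInterval(chrom, start, end),
                        unit=u,
                        repeat_count=(end - start) // 4,
                    )
                )
    found.sort(key=lambda m: (m.region.chrom, m.region.start, m.unit))
    return found


def _overlap_flags(
    regions: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per region: does it overlap (>0 bp) any feature?"""
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {f.chrom for f in features}:
        rows = sorted((f.start, f.end) for f in features if f.chrom == chrom)
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))
    flags = np.zeros(len(regions), dtype=bool)
    for i, region in enumerate(regions):
        entry = by_chrom.get(region.chrom)
        if entry is None:
            continue
        starts, ends, cummax_end = entry
        hi = int(np.searchsorted(starts, region.end, side="left"))
        lo = int(np.searchsorted(cummax_end, region.start, side="right"))
        for j in range(lo, hi):
            if min(ends[j], region.end) > max(starts[j], region.start):
                flags[i] = True
                break
    return flags


def region_overlap_enrichment(
    super_regions: Sequence[GenomicInterval],
    typical_regions: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
) -> dict:
    """Fisher enrichment of feature-containing regions, SUPER vs TYPICAL.

    The 2x2 table counts regions containing at least one feature versus
    none, per class; its margins equal the class sizes exactly.
    """
    if not super_regions or not typical_regions:
        raise ValueError("both region classes must be non-empty")
    s_flags = _overlap_flags(super_regions, features)
    t_flags = _overlap_flags(typical_regions, features)
    table = ContingencyTable2x2(
        a=int(s_flags.sum()),
        b=int(len(s_flags) - s_flags.sum()),
        c=int(t_flags.sum()),
        d=int(len(t_flags) - t_flags.sum()),
    )
    return {"table": table, "result": fisher_exact(table)}


def repeat_count_comparison(
    microsatellites: Sequence[Microsatellite],
    fli1_peaks: Sequence[Peak],
) -> EnrichmentResult:
    """Welch t comparison of repeat counts inside vs outside FLI1 peaks.

    Partitions microsatellites by any-overlap with a FLI1 peak. When one
    partition has fewer than two members only the group means are
    reported and the p-value is undefined.
    """
    if not microsatellites or not fli1_peaks:
        raise ValueError("microsatellites and fli1_peaks must be non-empty")
    regions = [m.region for m in microsatellites]
    inside = _overlap_flags(regions, [p.interval for p in fli1_peaks])
    counts = np.array([m.repeat_count for m in microsatellites], dtype=float)
    in_counts = counts[inside]
    out_counts = counts[~inside]
    details = {
        "n_in_peaks": int(len(in_counts)),
        "n_outside": int(len(out_counts)),
        "mean_in_peaks": float(in_counts.mean()) if len(in_counts) else float("nan"),
        "mean_outside": float(out_counts.mean()) if len(out_counts) else float("nan"),
    }
    if len(in_counts) < 2 or len(out_counts) < 2:
        return EnrichmentResult(
            name="repeat_count_comparison", p_value=None, details=details
        )
    try:
        welch = welch_t_test(in_counts, out_counts)
    except ValueError:
        # both partitions degenerate (zero variance): means only
        return EnrichmentResult(
            name="repeat_count_comparison", p_value=None, details=details
        )
    details["df"] = welch.details["df"]
    return EnrichmentResult(
        name="repeat_count_comparison",
        p_value=welch.p_value,
        statistic=welch.statistic,
        details=details,
    )
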