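"""Self-contained synthetic epigenomic landscape with ground truth.

The generator emits everything the pipeline consumes — genome sequence,
H3K27Ac signal track and peaks, H3K4me3 promoter peaks, FLI1 peaks, gene
models with expression, a dependency matrix and an IC50 table — together
with the planted truth, so every stage can be tested end to end without
external data.

The default configuration emulates the statistical structure of an Ewing
sarcoma H3K27Ac landscape at desk scale: a hockey-stick enhancer signal
distribution in which a small super-enhancer class (~30 kb regions with
a heavy-tailed ~10x density multiplier) carries most of the signal above
a large body of ~2 kb typical enhancers; GGAA microsatellites and FLI1
peaks placed preferentially in super-enhancers (region-containment odds
near 16 for FLI1 peaks and near 38 for microsatellites); long GGAA runs
under FLI1 peaks (mean ~7.3 repeat units) versus short runs elsewhere
(~2.3); elevated expression of super-enhancer target genes; and a
lineage-selective shift in dependency scores and IC50s.

Enhancers are placed with at least twice the default stitch distance
between them, so stitching recovers the planted enhancers exactly and
recovery statistics are not confounded by stitching ambiguity. All
randomness flows from one master seed through fixed-key substreams, so
adding a component never perturbs the draws of earlier ones.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GeneModel, Peak
from .tracks import SignalTrack
from .screens import DependencyMatrix, DrugResponseTable
from . import io as sio

# fixed substream keys: adding a component must not perturb earlier draws
_KEY_LAYOUT = 0
_KEY_STRENGTH = 1
_KEY_CONSTITUENTS = 2
_KEY_MSAT = 3
_KEY_GENES = 4
_KEY_SEQUENCE = 5  # combined with chromosome index
_KEY_TRACK = 6
_KEY_EXPRESSION = 7
_KEY_DEPENDENCY = 8
_KEY_IC50 = 9
_KEY_DECOYS = 10


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 17
    # genome
    n_chromosomes: int = 8
    chrom_length: int = 4_000_000
    # enhancer landscape
    n_typical: int = 1000
    n_super: int = 20
    typical_length_log_mean: float = math.log(2_000)
    typical_length_log_sd: float = 0.25
    super_length_log_mean: float = math.log(30_000)
    super_length_log_sd: float = 0.15
    spacing_bp: int = 25_000  # 2x the default stitch distance
    # signal model (RPM per base)
    background_density: float = 0.02
    enhancer_density: float = 0.5
    typical_strength_log_sd: float = 0.2
    super_multiplier: float = 10.0
    super_pareto_alpha: float = 2.0
    bin_width: int = 50
    depth_factor: float = 1.0
    # super-enhancer internal structure
    super_min_constituents: int = 3
    super_max_constituents: int = 6
    constituent_min_bp: int = 500
    constituent_gap_min_bp: int = 500
    constituent_gap_max_bp: int = 2_000
    # microsatellites and FLI1 peaks
    p_fli1_super: float = 0.85
    p_fli1_typical: float = 0.26
    p_msat_extra_super: float = 0.53  # msat without a FLI1 peak
    p_msat_extra_typical: float = 0.0
    msat_mean_repeats_in_fli1: float = 7.3
    msat_mean_repeats_outside: float = 2.3
    msat_background_per_mb: float = 3.0
    fli1_peak_width: int = 400
    # genes
    n_genes: int = 1_100
    se_target_fraction: float = 1.0
    target_tss_min_offset: int = 5_000
    target_tss_max_offset: int = 20_000
    gene_clearance_bp: int = 3_000
    decoy_tss_peak_fraction: float = 0.3
    decoy_peak_width: int = 1_500
    k4me3_peak_width: int = 1_200
    expression_log_mean: float = math.log(5.0)
    expression_log_sd: float = 1.0
    se_expression_fold: float = 4.0
    # screens
    n_screen_genes: int = 500
    n_lines: int = 40
    n_target_lines: int = 10
    n_selective_genes: int = 5
    n_driver_genes: int = 2
    dependency_effect: float = -2.5
    ic50_log_mean: float = 0.0  # log uM
    ic50_log_sd: float = 1.0
    ic50_target_multiplier: float = 0.2
    target_lineage: str = "EWING"
    other_lineage: str = "OTHER"

    def __post_init__(self) -> None:
        for name in ("n_typical", "n_super", "n_genes", "n_chromosomes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.n_lines < 4:
            raise ValueError("screens need at least 4 cell lines")
        if self.n_target_lines < 2 or self.n_lines - self.n_target_lines < 2:
            raise ValueError("need >= 2 cell lines per lineage group")
        if not (0 < self.ic50_target_multiplier):
            raise ValueError("ic50_target_multiplier must be positive")


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class TruthEnhancer:
    eid: str
    chrom: str
    start: int
    end: int
    klass: str  # "SUPER" or "TYPICAL"
    strength: float  # density above background, RPM/base
    constituents: List[Tuple[int, int]]

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class TruthMicrosatellite:
    chrom: str
    start: int
    unit: str
    repeat_count: int
    in_fli1_peak: bool
    enhancer_eid: Optional[str]

    @property
    def end(self) -> int:
        return self.start + 4 * self.repeat_count

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class TruthGene:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    expression: float
    role: str  # "se_target" or "background"
    target_eid: Optional[str] = None


@dataclass
class SyntheticTruth:
    seed: int
    enhancers: List[TruthEnhancer]
    microsatellites: List[TruthMicrosatellite]
    fli1_peaks: List[GenomicInterval]
    genes: List[TruthGene]
    selective_genes: List[str] = field(default_factory=list)
    driver_genes: List[str] = field(default_factory=list)
    line_labels: Dict[str, str] = field(default_factory=dict)

    @property
    def super_enhancers(self) -> List[TruthEnhancer]:
        return [e for e in self.enhancers if e.klass == "SUPER"]

    @property
    def typical_enhancers(self) -> List[TruthEnhancer]:
        return [e for e in self.enhancers if e.klass == "TYPICAL"]

    @property
    def se_target_genes(self) -> List[TruthGene]:
        return [g for g in self.genes if g.role == "se_target"]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "enhancers": [asdict(e) for e in self.enhancers],
            "microsatellites": [asdict(m) for m in self.microsatellites],
            "fli1_peaks": [
                {"chrom": p.chrom, "start": p.start, "end": p.end}
                for p in self.fli1_peaks
            ],
            "genes": [asdict(g) for g in self.genes],
            "selective_genes": self.selective_genes,
            "driver_genes": self.driver_genes,
            "line_labels": self.line_labels,
        }


# ---------------------------------------------------------------------------
# landscape generation


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _place_on_chromosome(
    lengths: Sequence[int], chrom_length: int, spacing: int, rng: np.random.Generator
) -> List[int]:
    """Start positions with every gap >= spacing; rejects infeasible packing."""
    k = len(lengths)
    required = int(sum(lengths)) + (k + 1) * spacing
    slack = chrom_length - required
    if slack < 0:
        raise ValueError(
            f"infeasible packing: {k} features of total {sum(lengths)} bp plus "
            f"{k + 1} gaps of {spacing} bp exceed chromosome length {chrom_length}"
        )
    weights = rng.random(k + 1)
    extra = np.floor(slack * weights / weights.sum()).astype(int)
    starts = []
    pos = 0
    for i, length in enumerate(lengths):
        pos += spacing + int(extra[i])
        starts.append(pos)
        pos += int(length)
    return starts


def _split_constituents(
    start: int, end: int, config: SyntheticConfig, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Cut a super-enhancer region into constituent peaks with small gaps."""
    length = end - start
    n_c = int(
        rng.integers(config.super_min_constituents, config.super_max_constituents + 1)
    )
    if length < 2 * n_c * config.constituent_min_bp:
        return [(start, end)]  # too small to subdivide
    gaps = rng.integers(
        config.constituent_gap_min_bp, config.constituent_gap_max_bp + 1, n_c - 1
    )
    max_gap_total = max(length // 3, 0)
    if gaps.sum() > max_gap_total and gaps.sum() > 0:
        gaps = np.maximum(1, (gaps * max_gap_total) // max(1, gaps.sum()))
    body = length - int(gaps.sum())
    base = config.constituent_min_bp
    weights = rng.random(n_c)
    widths = base + np.floor((body - base * n_c) * weights / weights.sum()).astype(int)
    widths[-1] += body - int(widths.sum())  # absorb rounding so hull is exact
    out = []
    pos = start
    for i in range(n_c):
        out.append((pos, pos + int(widths[i])))
        pos += int(widths[i])
        if i < n_c - 1:
            pos += int(gaps[i])
    assert out[-1][1] == end
    return out


def _draw_repeat_count(mean: float, rng: np.random.Generator) -> int:
    return 2 + int(rng.poisson(max(mean - 2.0, 0.0)))


def generate_landscape(config: SyntheticConfig) -> SyntheticTruth:
    """Plant enhancers, microsatellites, FLI1 peaks and genes.

    Deterministic given ``config.seed``. Sequence and track realizations
    are generated separately (:func:`synthesize_sequences`,
    :func:`simulate_tracks_and_peaks`) from the same truth.
    """
    n_total = config.n_typical + config.n_super
    rng_layout = _rng(config.seed, _KEY_LAYOUT)
    rng_strength = _rng(config.seed, _KEY_STRENGTH)
    rng_constituents = _rng(config.seed, _KEY_CONSTITUENTS)
    rng_msat = _rng(config.seed, _KEY_MSAT)
    rng_genes = _rng(config.seed, _KEY_GENES)
    rng_expr = _rng(config.seed, _KEY_EXPRESSION)

    # classes and lengths, shuffled so supers spread over chromosomes
    klasses = np.array(["TYPICAL"] * config.n_typical + ["SUPER"] * config.n_super)
    rng_layout.shuffle(klasses)
    lengths = np.where(
        klasses == "SUPER",
        np.exp(
            rng_layout.normal(
                config.super_length_log_mean, config.super_length_log_sd, n_total
            )
        ),
        np.exp(
            rng_layout.normal(
                config.typical_length_log_mean, config.typical_length_log_sd, n_total
            )
        ),
    ).astype(int)
    lengths = np.maximum(lengths, config.constituent_min_bp)

    enhancers: List[TruthEnhancer] = []
    for ci in range(config.n_chromosomes):
        idx = np.arange(ci, n_total, config.n_chromosomes)
        if len(idx) == 0:
            continue
        starts = _place_on_chromosome(
            lengths[idx], config.chrom_length, config.spacing_bp, rng_layout
        )
        chrom = _chrom_name(ci)
        for j, gi in enumerate(idx):
            start = starts[j]
            end = start + int(lengths[gi])
            klass = str(klasses[gi])
            if klass == "SUPER":
                strength = (
                    config.enhancer_density
                    * config.super_multiplier
                    * (1.0 + rng_strength.pareto(config.super_pareto_alpha))
                )
                constituents = _split_constituents(start, end, config, rng_constituents)
            else:
                strength = config.enhancer_density * float(
                    np.exp(rng_strength.normal(0.0, config.typical_strength_log_sd))
                )
                constituents = [(start, end)]
            enhancers.append(
                TruthEnhancer(
                    eid=f"{chrom}:{start}-{end}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    klass=klass,
                    strength=float(strength),
                    constituents=constituents,
                )
            )
    enhancers.sort(key=lambda e: (e.chrom, e.start))

    # microsatellites and FLI1 peaks inside enhancers
    msats: List[TruthMicrosatellite] = []
    fli1_peaks: List[GenomicInterval] = []
    for enh in enhancers:
        is_super = enh.klass == "SUPER"
        p_fli1 = config.p_fli1_super if is_super else config.p_fli1_typical
        p_extra = config.p_msat_extra_super if is_super else config.p_msat_extra_typical
        has_fli1 = rng_msat.random() < p_fli1
        has_extra = (not has_fli1) and rng_msat.random() < p_extra
        if not (has_fli1 or has_extra):
            continue
        mean = (
            config.msat_mean_repeats_in_fli1
            if has_fli1
            else config.msat_mean_repeats_outside
        )
        count = _draw_repeat_count(mean, rng_msat)
        cons = enh.constituents[int(rng_msat.integers(0, len(enh.constituents)))]
        margin = 100
        limit = cons[1] - margin - 4 * count
        if limit <= cons[0] + margin:  # constituent too small for this run
            count = max(2, (cons[1] - cons[0] - 2 * margin) // 4)
            limit = cons[1] - margin - 4 * count
        start = int(rng_msat.integers(cons[0] + margin, max(cons[0] + margin + 1, limit)))
        unit = "GGAA" if rng_msat.random() < 0.5 else "TTCC"
        msats.append(
            TruthMicrosatellite(
                chrom=enh.chrom,
                start=start,
                unit=unit,
                repeat_count=count,
                in_fli1_peak=has_fli1,
                enhancer_eid=enh.eid,
            )
        )
        if has_fli1:
            center = start + 2 * count
            half = config.fli1_peak_width // 2
            fli1_peaks.append(
                GenomicInterval(enh.chrom, max(0, center - half), center + half)
            )

    # background microsatellites, away from enhancers
    genome_mb = config.n_chromosomes * config.chrom_length / 1e6
    n_bg = int(rng_msat.poisson(config.msat_background_per_mb * genome_mb))
    enh_bounds: Dict[str, np.ndarray] = {}
    for ci in range(config.n_chromosomes):
        chrom = _chrom_name(ci)
        rows = [(e.start, e.end) for e in enhancers if e.chrom == chrom]
        enh_bounds[chrom] = np.array(rows, dtype=np.int64).reshape(-1, 2)
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in enh_bounds}
    placed = 0
    attempts = 0
    while placed < n_bg and attempts < 20 * n_bg + 100:
        attempts += 1
        ci = int(rng_msat.integers(0, config.n_chromosomes))
        chrom = _chrom_name(ci)
        count = _draw_repeat_count(config.msat_mean_repeats_outside, rng_msat)
        pos = int(rng_msat.integers(1_000, config.chrom_length - 1_000 - 4 * count))
        bounds = enh_bounds[chrom]
        if len(bounds) and np.any(
            (pos < bounds[:, 1] + 500) & (pos + 4 * count > bounds[:, 0] - 500)
        ):
            continue
        if any(pos < e + 200 and pos + 4 * count > s - 200 for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((pos, pos + 4 * count))
        unit = "GGAA" if rng_msat.random() < 0.5 else "TTCC"
        msats.append(
            TruthMicrosatellite(
                chrom=chrom,
                start=pos,
                unit=unit,
                repeat_count=count,
                in_fli1_peak=False,
                enhancer_eid=None,
            )
        )
        placed += 1
    msats.sort(key=lambda m: (m.chrom, m.start))

    # genes: one target per super (fractionally), background genes in gaps
    genes: List[TruthGene] = []
    gene_counter = 0
    for enh in enhancers:
        if enh.klass != "SUPER":
            continue
        if rng_genes.random() >= config.se_target_fraction:
            continue
        offset = int(
            rng_genes.integers(
                config.target_tss_min_offset, config.target_tss_max_offset + 1
            )
        )
        side = 1 if rng_genes.random() < 0.5 else -1
        tss = enh.end + offset if side > 0 else enh.start - offset
        if not (1_000 <= tss < config.chrom_length - 1_000):
            tss = enh.end + offset if side < 0 else enh.start - offset
        strand = "+" if rng_genes.random() < 0.5 else "-"
        gene_counter += 1
        genes.append(
            TruthGene(
                gene_id=f"G{gene_counter:05d}",
                chrom=enh.chrom,
                tss=int(tss),
                strand=strand,
                expression=0.0,
                role="se_target",
                target_eid=enh.eid,
            )
        )

    n_background = max(0, config.n_genes - len(genes))
    segments = []  # (chrom, lo, hi) regions allowed for background TSS
    clearance = config.gene_clearance_bp
    for ci in range(config.n_chromosomes):
        chrom = _chrom_name(ci)
        bounds = enh_bounds[chrom]
        prev = 1_000
        for s, e in bounds:
            lo, hi = prev, int(s) - clearance
            if hi > lo:
                segments.append((chrom, lo, hi))
            prev = int(e) + clearance
        if config.chrom_length - 1_000 > prev:
            segments.append((chrom, prev, config.chrom_length - 1_000))
    seg_lengths = np.array([hi - lo for _, lo, hi in segments], dtype=float)
    total = seg_lengths.sum()
    offsets = np.sort(rng_genes.random(n_background)) * total
    cum = np.cumsum(seg_lengths)
    for off in offsets:
        si = int(np.searchsorted(cum, off, side="right"))
        chrom, lo, hi = segments[si]
        pos = lo + int(off - (cum[si] - seg_lengths[si]))
        strand = "+" if rng_genes.random() < 0.5 else "-"
        gene_counter += 1
        genes.append(
            TruthGene(
                gene_id=f"G{gene_counter:05d}",
                chrom=chrom,
                tss=min(pos, config.chrom_length - 1_001),
                strand=strand,
                expression=0.0,
                role="background",
            )
        )

    # expression: lognormal, fold-shifted for super-enhancer targets
    for gene in genes:
        value = float(
            np.exp(rng_expr.normal(config.expression_log_mean, config.expression_log_sd))
        )
        if gene.role == "se_target":
            value *= config.se_expression_fold
        gene.expression = value
    genes.sort(key=lambda g: (g.chrom, g.tss))

    return SyntheticTruth(
        seed=config.seed,
        enhancers=enhancers,
        microsatellites=msats,
        fli1_peaks=sorted(fli1_peaks, key=lambda p: (p.chrom, p.start)),
        genes=genes,
    )


# ---------------------------------------------------------------------------
# sequence and track realizations


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def synthesize_sequences(truth: SyntheticTruth, config: SyntheticConfig) -> Dict[str, str]:
    """Random genome with the planted microsatellite runs spliced in."""
    sequences: Dict[str, str] = {}
    msats_by_chrom: Dict[str, List[TruthMicrosatellite]] = {}
    for m in truth.microsatellites:
        msats_by_chrom.setdefault(m.chrom, []).append(m)
    for ci in range(config.n_chromosomes):
        chrom = _chrom_name(ci)
        rng = _rng(config.seed, _KEY_SEQUENCE, ci)
        arr = _BASES[rng.integers(0, 4, config.chrom_length, dtype=np.uint8)]
        buf = bytearray(arr.tobytes())
        for m in msats_by_chrom.get(chrom, []):
            run = (m.unit * m.repeat_count).encode()
            buf[m.start : m.start + len(run)] = run
        sequences[chrom] = buf.decode()
    return sequences


def simulate_tracks_and_peaks(
    truth: SyntheticTruth, config: SyntheticConfig
) -> dict:
    """Noisy H3K27Ac track plus H3K27Ac/H3K4me3/FLI1 peak calls.

    The expected density is background plus the planted strength over
    each constituent (and a small promoter bump at decoy TSS peaks); the
    realized track draws Poisson counts per fixed-width bin and rescales
    to RPM per base.
    """
    rng_track = _rng(config.seed, _KEY_TRACK)
    rng_decoy = _rng(config.seed, _KEY_DECOYS)

    # decoy promoter H3K27Ac peaks at a fraction of TSSs (exercise exclusion)
    decoy_peaks: List[Peak] = []
    k4_peaks: List[Peak] = []
    half_decoy = config.decoy_peak_width // 2
    half_k4 = config.k4me3_peak_width // 2
    promoter_density = 0.3 * config.enhancer_density
    for gene in truth.genes:
        k4_peaks.append(
            Peak(
                GenomicInterval(
                    gene.chrom, max(0, gene.tss - half_k4), gene.tss + half_k4
                ),
                score=1.0,
                name=f"k4_{gene.gene_id}",
            )
        )
        if rng_decoy.random() < config.decoy_tss_peak_fraction:
            decoy_peaks.append(
                Peak(
                    GenomicInterval(
                        gene.chrom, max(0, gene.tss - half_decoy), gene.tss + half_decoy
                    ),
                    score=promoter_density,
                    name=f"decoy_{gene.gene_id}",
                )
            )

    w = config.bin_width
    depth = config.depth_factor
    segments: Dict[str, tuple] = {}
    for ci in range(config.n_chromosomes):
        chrom = _chrom_name(ci)
        n_bins = (config.chrom_length + w - 1) // w
        expected = np.full(n_bins, config.background_density * w, dtype=float)

        def _add(start: int, end: int, density: float) -> None:
            b0, b1 = start // w, (end - 1) // w
            if b0 == b1:
                expected[b0] += density * (end - start)
                return
            expected[b0] += density * ((b0 + 1) * w - start)
            expected[b1] += density * (end - b1 * w)
            if b1 > b0 + 1:
                expected[b0 + 1 : b1] += density * w
        for enh in truth.enhancers:
            if enh.chrom != chrom:
                continue
            for s, e in enh.constituents:
                _add(s, e, enh.strength)
        for peak in decoy_peaks:
            if peak.chrom == chrom:
                _add(peak.start, peak.end, peak.score)

        counts = rng_track.poisson(expected * depth)
        values = counts / (w * depth)
        starts = np.arange(n_bins, dtype=np.int64) * w
        ends = np.minimum(starts + w, config.chrom_length)
        segments[chrom] = (starts, ends, values.astype(float))
    track = SignalTrack(segments)

    k27_peaks: List[Peak] = []
    for enh in truth.enhancers:
        for i, (s, e) in enumerate(enh.constituents):
            k27_peaks.append(
                Peak(
                    GenomicInterval(enh.chrom, s, e),
                    score=enh.strength,
                    name=f"k27_{enh.eid}_{i}",
                )
            )
    k27_peaks.extend(decoy_peaks)
    k27_peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    k4_peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    fli1 = [
        Peak(region, score=1.0, name=f"fli1_{i}")
        for i, region in enumerate(truth.fli1_peaks)
    ]
    return {
        "track": track,
        "k27ac_peaks": k27_peaks,
        "k4me3_peaks": k4_peaks,
        "fli1_peaks": fli1,
    }


# ---------------------------------------------------------------------------
# expression and screens


def simulate_expression_and_screens(
    truth: SyntheticTruth, config: SyntheticConfig
) -> dict:
    """Expression table, dependency matrix and IC50 table with planted effects.

    Updates ``truth`` in place with the selective/driver gene ids and the
    cell-line lineage labels it plants.
    """
    rng_dep = _rng(config.seed, _KEY_DEPENDENCY)
    rng_ic50 = _rng(config.seed, _KEY_IC50)

    expression = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in truth.genes],
            "expression": [g.expression for g in truth.genes],
        }
    )

    # screen gene universe: super-enhancer targets first, then background
    target_ids = [g.gene_id for g in truth.se_target_genes]
    background_ids = [g.gene_id for g in truth.genes if g.role == "background"]
    universe = (target_ids + background_ids)[: config.n_screen_genes]
    if len(universe) < config.n_screen_genes:
        universe += [
            f"X{i:05d}" for i in range(config.n_screen_genes - len(universe))
        ]
    selective = universe[: config.n_selective_genes]
    drivers = selective[: config.n_driver_genes]

    target_lines = [f"EW_{i + 1:02d}" for i in range(config.n_target_lines)]
    other_lines = [
        f"OT_{i + 1:02d}" for i in range(config.n_lines - config.n_target_lines)
    ]
    lines = target_lines + other_lines
    labels = pd.Series(
        [config.target_lineage] * len(target_lines)
        + [config.other_lineage] * len(other_lines),
        index=lines,
        name="lineage",
    )

    scores = rng_dep.normal(0.0, 1.0, size=(len(universe), len(lines)))
    sel_idx = [universe.index(g) for g in selective]
    scores[np.ix_(sel_idx, np.arange(len(target_lines)))] += config.dependency_effect
    dependency = DependencyMatrix(
        scores=pd.DataFrame(scores, index=universe, columns=lines), lineages=labels
    )

    ic50 = np.exp(rng_ic50.normal(config.ic50_log_mean, config.ic50_log_sd, len(lines)))
    ic50[: len(target_lines)] *= config.ic50_target_multiplier
    drug_table = DrugResponseTable(
        pd.DataFrame(
            {"line": lines, "lineage": labels.to_numpy(), "ic50": ic50}
        )
    )

    truth.selective_genes = list(selective)
    truth.driver_genes = list(drivers)
    truth.line_labels = dict(labels)
    return {
        "expression": expression,
        "dependency": dependency,
        "drug_table": drug_table,
    }


# ---------------------------------------------------------------------------
# one-call dataset and file emission


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: SyntheticTruth
    track: SignalTrack
    k27ac_peaks: List[Peak]
    k4me3_peaks: List[Peak]
    fli1_peaks: List[Peak]
    genes: List[GeneModel]
    expression: pd.DataFrame
    dependency: DependencyMatrix
    drug_table: DrugResponseTable
    sequences: Optional[Dict[str, str]] = None


def simulate_dataset(
    config: Optional[SyntheticConfig] = None, with_sequence: bool = False
) -> SyntheticDataset:
    """Generate the complete synthetic dataset for one configuration."""
    config = config or SyntheticConfig()
    truth = generate_landscape(config)
    tracks = simulate_tracks_and_peaks(truth, config)
    screens = simulate_expression_and_screens(truth, config)
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            tss=GenomicInterval(g.chrom, g.tss, g.tss + 1, g.strand),
            expression=g.expression,
        )
        for g in truth.genes
    ]
    sequences = synthesize_sequences(truth, config) if with_sequence else None
    return SyntheticDataset(
        config=config,
        truth=truth,
        track=tracks["track"],
        k27ac_peaks=tracks["k27ac_peaks"],
        k4me3_peaks=tracks["k4me3_peaks"],
        fli1_peaks=tracks["fli1_peaks"],
        genes=genes,
        expression=screens["expression"],
        dependency=screens["dependency"],
        drug_table=screens["drug_table"],
        sequences=sequences,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> Dict[str, Path]:
    """Emit all dataset files (plain text, seed recorded in headers)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = dataset.config.seed
    header = f"seed={seed}"
    paths: Dict[str, Path] = {}

    if dataset.sequences is None:
        dataset.sequences = synthesize_sequences(dataset.truth, dataset.config)
    paths["genome"] = out / "genome.fa"
    sio.write_fasta(dataset.sequences, paths["genome"])

    paths["genes"] = out / "genes.tsv"
    sio.write_genes_tsv(dataset.genes, paths["genes"], header=header)

    paths["k27ac_track"] = out / "k27ac.bedgraph"
    sio.write_bedgraph(dataset.track, paths["k27ac_track"], header=header)
    for key, peaks in (
        ("k27ac_peaks", dataset.k27ac_peaks),
        ("k4me3_peaks", dataset.k4me3_peaks),
        ("fli1_peaks", dataset.fli1_peaks),
    ):
        paths[key] = out / f"{key}.bed"
        sio.write_bed(peaks, paths[key], header=header)

    paths["expression"] = out / "expression.tsv"
    with open(paths["expression"], "w") as fh:
        fh.write(f"# {header}\n")
        dataset.expression.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    paths["dependency"] = out / "dependency.tsv"
    with open(paths["dependency"], "w") as fh:
        fh.write(f"# {header}\n")
        dataset.dependency.scores.to_csv(
            fh, sep="\t", index_label="gene_id", float_format="%.6g"
        )
    paths["labels"] = out / "labels.tsv"
    with open(paths["labels"], "w") as fh:
        fh.write(f"# {header}\n")
        dataset.dependency.lineages.to_csv(fh, sep="\t", index_label="line")

    paths["ic50"] = out / "ic50.tsv"
    with open(paths["ic50"], "w") as fh:
        fh.write(f"# {header}\n")
        dataset.drug_table.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths
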