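"""Readers and writers for the plain-text formats the pipeline consumes.

BED and bedGraph are parsed directly (they are line formats with no
ambiguity); gene tables and screen tables go through pandas; FASTA access
goes through pyfaidx behind a minimal ``fetch``/``sequence`` contract.
Comment lines starting with ``#`` or ``track`` are skipped everywhere so
generated files can carry a seed header.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GeneModel, Peak, sort_key
from .tracks import SignalTrack

logger = logging.getLogger(__name__)


def _data_lines(path):
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def read_bed(path, expected_columns: int = 3) -> List[Peak]:
    """Read a BED3+ file into peaks sorted by (chrom, start, end).

    Column 5 (score) is used when present, else 0. Malformed coordinates
    are rejected with the offending line number; an empty file yields an
    empty list.
    """
    if expected_columns < 3:
        raise ValueError("expected_columns must be >= 3")
    peaks: List[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < expected_columns:
            raise ValueError(
                f"{path}:{lineno}: expected >= {expected_columns} columns, "
                f"got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end or start < 0:
            raise ValueError(
                f"{path}:{lineno}: invalid coordinates {start} >= {end}"
            )
        name = fields[3] if len(fields) > 3 else ""
        score = 0.0
        if len(fields) > 4 and fields[4] not in ("", "."):
            score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else "."
        peaks.append(
            Peak(
                interval=GenomicInterval(fields[0], start, end, strand),
                score=score,
                name=name,
            )
        )
    peaks.sort(key=lambda p: sort_key(p.interval))
    return peaks


def write_bed(peaks: Iterable[Peak], path, extra_columns=None, header: str = "") -> None:
    """Write peaks as BED6 (+ optional extra columns per record)."""
    peaks = list(peaks)
    extras = list(extra_columns) if extra_columns is not None else [()] * len(peaks)
    if len(extras) != len(peaks):
        raise ValueError("extra_columns length mismatch")
    with open(path, "w") as out:
        if header:
            out.write(f"# {header}\n")
        for peak, extra in zip(peaks, extras):
            iv = peak.interval
            fields = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                peak.name or ".",
                format(peak.score, ".6g"),
                iv.strand,
            ]
            fields.extend(str(x) for x in extra)
            out.write("\t".join(fields) + "\n")


def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph into a signal track.

    Intervals within a chromosome must be non-overlapping; the first
    offending pair is named in the error.
    """
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed record") from exc
        if start >= end or start < 0:
            raise ValueError(f"{path}:{lineno}: invalid coordinates")
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative signal value")
        records.append((fields[0], start, end, value))
    try:
        return SignalTrack.from_segments(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path, header: str = "") -> None:
    with open(path, "w") as out:
        if header:
            out.write(f"# {header}\n")
        for chrom, start, end, value in track.iter_segments():
            out.write(f"{chrom}\t{start}\t{end}\t{format(value, '.6g')}\n")


# ---------------------------------------------------------------------------
# gene tables

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "expression"]


def read_genes_tsv(path) -> List[GeneModel]:
    """Read a gene table (gene_id, chrom, tss, strand, expression)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.tss)
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                tss=GenomicInterval(row.chrom, tss, tss + 1, str(row.strand)),
                expression=float(row.expression),
            )
        )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene ids")
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path, header: str = "") -> None:
    with open(path, "w") as out:
        if header:
            out.write(f"# {header}\n")
        out.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            out.write(
                f"{g.gene_id}\t{g.tss.chrom}\t{g.tss_position}\t{g.tss.strand}\t"
                f"{format(g.expression, '.6g')}\n"
            )


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> Dict[str, set]:
    """Read GMT gene sets: name <tab> description <tab> id1 <tab> id2 ..."""
    sets: Dict[str, set] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 fields")
        sets[fields[0]] = set(fields[2:])
    return sets


# ---------------------------------------------------------------------------
# screen tables

def read_dependency_tsv(matrix_path, labels_path):
    """Read a gene x cell-line score matrix plus a line->lineage label table."""
    from .screens import DependencyMatrix

    scores = pd.read_csv(matrix_path, sep="\t", comment="#", index_col="gene_id")
    labels = pd.read_csv(labels_path, sep="\t", comment="#", index_col="line")[
        "lineage"
    ]
    return DependencyMatrix(scores=scores, lineages=labels)


def read_ic50_tsv(path):
    """Read a per-line IC50 table (line, lineage, ic50)."""
    from .screens import DrugResponseTable

    return DrugResponseTable(pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------------------
# sequence access

class FastaSource:
    """Indexed FASTA reader contract: ``fetch(chrom, start, end)`` uppercase."""

    def __init__(self, path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)

    def chroms(self) -> List[str]:
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start:end])

    def sequence(self, chrom: str) -> str:
        return str(self._fasta[chrom][:])

    def length(self, chrom: str) -> int:
        return len(self._fasta[chrom])


class DictSource:
    """In-memory sequence source satisfying the same contract."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])


def as_sequence_source(source):
    if hasattr(source, "sequence") and hasattr(source, "chroms"):
        return source
    if isinstance(source, Mapping):
        return DictSource(source)
    raise TypeError("expected a sequence source or a chrom->sequence mapping")


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as out:
        for chrom in sequences:
            out.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
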