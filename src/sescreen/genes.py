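"""Assignment of transcriptionally active genes to enhancers.

A gene is linked to an enhancer when its TSS lies within a distance
window of the enhancer boundary (zero when the TSS falls inside the
region) and its expression clears an activity threshold. Genes linked to
at least one super-enhancer are SUPER-associated regardless of any
typical-enhancer links, matching the usual nomination of super-enhancer
genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np

from .enhancers import EnhancerClass, EnhancerRanking
from .intervals import GeneModel

DEFAULT_WINDOW_BP = 50_000
DEFAULT_EXPRESSION_THRESHOLD = 1.0


@dataclass(frozen=True)
class GeneLink:
    enhancer_id: str
    gene_id: str
    distance: int
    enhancer_klass: EnhancerClass
    enhancer_signal: float


@dataclass(frozen=True)
class GeneAssignment:
    links: Tuple[GeneLink, ...]
    super_genes: FrozenSet[str]
    typical_genes: FrozenSet[str]
    window_bp: int
    expression_threshold: float


def assign_genes(
    ranking: EnhancerRanking,
    genes: Sequence[GeneModel],
    window_bp: int = DEFAULT_WINDOW_BP,
    expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> GeneAssignment:
    """Link active genes to enhancers within ``window_bp`` of their TSS."""
    if window_bp < 0:
        raise ValueError("window_bp must be nonnegative")
    if any(e.klass is None for e in ranking.enhancers):
        raise ValueError("call_super must be applied before gene assignment")

    by_chrom: Dict[str, list] = {}
    for enh in ranking.enhancers:
        by_chrom.setdefault(enh.region.chrom, []).append(enh)
    arrays = {}
    for chrom, enhs in by_chrom.items():
        enhs.sort(key=lambda e: (e.region.start, e.region.end))
        arrays[chrom] = (
            np.array([e.region.start for e in enhs], dtype=np.int64),
            np.array([e.region.end for e in enhs], dtype=np.int64),
            enhs,
        )

    links: List[GeneLink] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.expression < expression_threshold:
            continue
        entry = arrays.get(gene.tss.chrom)
        if entry is None:
            continue
        starts, ends, enhs = entry
        t = gene.tss_position
        overlap = np.minimum(t + 1, ends) - np.maximum(t, starts)
        dist = np.where(overlap > 0, 0, np.maximum(t - ends, starts - (t + 1)))
        for j in np.flatnonzero(dist <= window_bp):
            enh = enhs[int(j)]
            links.append(
                GeneLink(
                    enhancer_id=enh.eid,
                    gene_id=gene.gene_id,
                    distance=int(dist[j]),
                    enhancer_klass=enh.klass,
                    enhancer_signal=float(enh.signal),
                )
            )

    sets = class_gene_sets_from_links(links)
    return GeneAssignment(
        links=tuple(links),
        super_genes=frozenset(sets["super_genes"]),
        typical_genes=frozenset(sets["typical_genes"]),
        window_bp=window_bp,
        expression_threshold=expression_threshold,
    )


def class_gene_sets_from_links(links: Sequence[GeneLink]) -> dict:
    super_genes = {l.gene_id for l in links if l.enhancer_klass is EnhancerClass.SUPER}
    typical_genes = {
        l.gene_id for l in links if l.enhancer_klass is EnhancerClass.TYPICAL
    } - super_genes
    return {"super_genes": super_genes, "typical_genes": typical_genes}


def class_gene_sets(assignment: GeneAssignment) -> dict:
    """Disjoint SUPER-associated / TYPICAL-associated gene-id sets with counts.

    A gene linked to both classes counts as SUPER-associated only.
    """
    sets = class_gene_sets_from_links(assignment.links)
    sets["n_super_genes"] = len(sets["super_genes"])
    sets["n_typical_genes"] = len(sets["typical_genes"])
    return sets
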