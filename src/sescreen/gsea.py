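"""Gene set enrichment on enhancer-signal-ranked gene lists.

Genes are ranked by the H3K27Ac signal of their linked enhancers (max
over links) and a query set is tested for concentration at the top of
the list with the weighted Kolmogorov-Smirnov-like running-sum statistic.
Because the ranking derives from a single sample's enhancer signal there
are no phenotype labels to permute; significance comes from a gene-set
permutation null (random sets of the same size drawn from the list).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .enhancers import EnhancerRanking
from .genes import GeneAssignment
from .intervals import GeneModel
from .stats import EnrichmentResult, mann_whitney

DEFAULT_WEIGHT_EXPONENT = 1.0
DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_SEED = 17


@dataclass(frozen=True)
class RankedGeneList:
    """Gene ids ordered by non-increasing metric."""

    ids: Tuple[str, ...]
    metrics: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.metrics):
            raise ValueError("ids/metrics length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("gene ids must be unique")
        if np.any(np.diff(self.metrics) > 0):
            raise ValueError("metrics must be non-increasing")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class GseaResult:
    es: float
    nes: float
    p_value: float
    running_sum: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def rank_genes_by_enhancer_signal(
    assignment: GeneAssignment, ranking: EnhancerRanking
) -> RankedGeneList:
    """Rank genes by the maximum signal over their linked enhancers.

    Ties are broken lexicographically by gene id; genes without links do
    not appear.
    """
    signal_by_eid = {e.eid: float(e.signal) for e in ranking.enhancers}
    metric: Dict[str, float] = {}
    for link in assignment.links:
        if link.enhancer_id not in signal_by_eid:
            raise KeyError(f"link references unknown enhancer {link.enhancer_id}")
        s = signal_by_eid[link.enhancer_id]
        if s > metric.get(link.gene_id, -np.inf):
            metric[link.gene_id] = s
    ordered = sorted(metric, key=lambda g: (-metric[g], g))
    return RankedGeneList(
        ids=tuple(ordered), metrics=np.array([metric[g] for g in ordered])
    )


def _hit_mask(ranked: RankedGeneList, gene_set: Set[str]) -> np.ndarray:
    return np.array([g in gene_set for g in ranked.ids], dtype=bool)


def _pick_extremum(hi: float, lo: float) -> float:
    """Signed extremum with ties resolved to the positive deviation.

    The tolerance absorbs floating-point noise so the full running-sum and
    the hits-only evaluation agree on exactly symmetric excursions.
    """
    tol = 1e-12 * max(1.0, hi, -lo)
    return hi if hi + lo >= -tol else lo


def _es_from_hits(
    abs_weights: np.ndarray, hit_idx: np.ndarray, n_total: int
) -> float:
    """Signed extremum of the running sum, from sorted hit indices only.

    ``abs_weights`` is |metric|^w over the full list. Between hits the sum
    falls linearly, so candidate extrema are the value just after each hit
    and the value just before each hit.
    """
    k = len(hit_idx)
    denom = abs_weights[hit_idx].sum()
    if denom == 0:
        # all hit metrics are zero: fall back to equal hit increments
        hit_increment = np.full(k, 1.0 / k)
    else:
        hit_increment = abs_weights[hit_idx] / denom
    miss = 1.0 / (n_total - k)
    cumw = np.cumsum(hit_increment)
    j = np.arange(1, k + 1)
    at_hit = cumw - (hit_idx + 1 - j) * miss
    before_hit = np.concatenate(([0.0], cumw[:-1])) - (hit_idx - (j - 1)) * miss
    hi = float(at_hit.max())
    lo = float(min(before_hit.min(), 0.0))
    return _pick_extremum(hi, lo)


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> dict:
    """Running-sum enrichment score of ``gene_set`` in the ranked list.

    Walking the list top-down, set members add ``|metric|^w / sum`` and
    non-members subtract ``1/(N - N_set)``; the score is the running-sum
    value of maximal absolute deviation from zero (signed).
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be nonnegative")
    gene_set = set(gene_set)
    hits = _hit_mask(ranked, gene_set)
    k = int(hits.sum())
    if k == 0:
        raise ValueError("gene_set is disjoint from the ranked list")
    n = len(ranked)
    if k == n:
        # every gene is a hit: all increments, score 1 at the end
        running = np.cumsum(np.abs(ranked.metrics) ** weight_exponent)
        running = running / running[-1] if running[-1] > 0 else np.cumsum(
            np.full(n, 1.0 / n)
        )
        return {"es": 1.0, "running_sum": running}
    abs_w = np.abs(ranked.metrics) ** weight_exponent
    denom = abs_w[hits].sum()
    steps = np.where(
        hits,
        (abs_w / denom) if denom > 0 else (1.0 / k),
        -1.0 / (n - k),
    )
    running = np.cumsum(steps)
    hi = float(running.max())
    lo = float(min(running.min(), 0.0))
    return {"es": _pick_extremum(hi, lo), "running_sum": running}


def gsea_permutation_p(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> GseaResult:
    """Gene-set-permutation p-value and normalized enrichment score.

    The null draws random sets of the same size (without replacement)
    from the list; p = (1 + #{|es_null| >= |es_obs|}) / (1 + B), so it is
    never zero. NES divides the observed score by the mean |null score|
    of matching sign.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    gene_set = set(gene_set) & set(ranked.ids)
    if not gene_set:
        raise ValueError("gene_set is disjoint from the ranked list")
    n = len(ranked)
    k = len(gene_set)
    if k >= n:
        raise ValueError("gene_set must be smaller than the ranked list")

    obs = enrichment_score(ranked, gene_set, weight_exponent)
    es_obs = obs["es"]
    abs_w = np.abs(ranked.metrics) ** weight_exponent
    rng = np.random.default_rng(seed)
    es_null = np.empty(n_permutations)
    for b in range(n_permutations):
        hit_idx = np.sort(rng.choice(n, size=k, replace=False))
        es_null[b] = _es_from_hits(abs_w, hit_idx, n)
    p = (1 + int(np.sum(np.abs(es_null) >= abs(es_obs)))) / (1 + n_permutations)
    same_sign = es_null[np.sign(es_null) == np.sign(es_obs)]
    nes = es_obs / np.abs(same_sign).mean() if len(same_sign) else float("nan")
    return GseaResult(
        es=es_obs,
        nes=float(nes),
        p_value=p,
        running_sum=obs["running_sum"],
        n_permutations=n_permutations,
        seed=seed,
    )


def expression_by_class(
    genes: Sequence[GeneModel], assignment: GeneAssignment
) -> dict:
    """Expression summaries for SUPER- vs TYPICAL-associated genes.

    Reports n, median and quartiles per class and a one-sided
    Mann-Whitney test of SUPER > TYPICAL. With fewer than two genes in a
    class the quartiles degenerate and the test is not performed.
    """
    expr = {g.gene_id: g.expression for g in genes}
    super_vals = sorted(expr[g] for g in assignment.super_genes if g in expr)
    typical_vals = sorted(expr[g] for g in assignment.typical_genes if g in expr)
    if not super_vals or not typical_vals:
        raise ValueError("both gene classes must be non-empty")

    def summary(vals):
        arr = np.array(vals)
        return {
            "n": int(len(arr)),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }

    out = {"super": summary(super_vals), "typical": summary(typical_vals)}
    if len(super_vals) >= 2 and len(typical_vals) >= 2:
        out["test"] = mann_whitney(super_vals, typical_vals, alternative="greater")
    else:
        out["test"] = None
    return out
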