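"""Lineage-selective dependency scoring and screen intersection.

The dependency input is a gene x cell-line matrix of gene-level depletion
scores (more negative = more depleted, e.g. ATARiS-style solutions from a
pooled shRNA screen), with a lineage label per line. Selectivity for a
target lineage is scored with the signal-to-noise ratio

    snr = (mean_target - mean_other) / (sd_target + sd_other)

with each standard deviation floored at 0.2x the larger group-mean
magnitude (the usual variance floor for expression-like data, and the
symmetric form that keeps snr antisymmetric under swapping the groups).
Significance comes from permuting line labels, the only null the matrix
itself supports. Drug response (IC50 per line) is compared between
lineages with the rank-based Mann-Whitney test, which is invariant to
the log transform used for summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .stats import EnrichmentResult, mann_whitney

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_SEED = 17
SNR_FLOOR_FRACTION = 0.2
SNR_FLOOR_MIN = 1e-8


@dataclass
class DependencyMatrix:
    """Gene x cell-line dependency scores plus per-line lineage labels."""

    scores: pd.DataFrame  # index = gene ids, columns = line ids
    lineages: pd.Series  # index = line ids, values = lineage labels

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValueError("duplicate gene or line ids")
        missing = set(self.scores.columns) - set(self.lineages.index)
        if missing:
            raise ValueError(f"unlabeled cell lines: {sorted(missing)[:5]}")
        self.lineages = self.lineages.loc[self.scores.columns]

    @property
    def gene_ids(self) -> List[str]:
        return list(self.scores.index)


@dataclass(frozen=True)
class SelectivityResult:
    table: pd.DataFrame  # index = gene ids; columns snr, rank, p_value
    target_lineage: str
    n_permutations: int
    seed: int

    def top_genes(self, k: int) -> List[str]:
        return list(self.table.sort_values("rank").index[:k])


def _snr(values: np.ndarray, target_mask: np.ndarray) -> np.ndarray:
    """Vectorized floored signal-to-noise per gene (rows of ``values``)."""
    t = values[:, target_mask]
    o = values[:, ~target_mask]
    mt, mo = t.mean(axis=1), o.mean(axis=1)
    st = t.std(axis=1, ddof=1)
    so = o.std(axis=1, ddof=1)
    floor = np.maximum(
        SNR_FLOOR_FRACTION * np.maximum(np.abs(mt), np.abs(mo)), SNR_FLOOR_MIN
    )
    st = np.maximum(st, floor)
    so = np.maximum(so, floor)
    return (mt - mo) / (st + so)


def signal_to_noise_selectivity(
    matrix: DependencyMatrix,
    target_lineage: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> SelectivityResult:
    """Rank genes by target-lineage depletion selectivity.

    Rank 1 is the most negative snr (most selectively depleted). Per-gene
    p-values count label permutations with snr at least as negative as
    observed, with the +1 correction.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    labels = matrix.lineages.to_numpy()
    target_mask = labels == target_lineage
    if target_mask.sum() == 0:
        raise ValueError(f"lineage {target_lineage!r} absent from the matrix")
    if target_mask.sum() < 2 or (~target_mask).sum() < 2:
        raise ValueError("need >= 2 cell lines per lineage group")

    values = matrix.scores.to_numpy(dtype=float)
    snr_obs = _snr(values, target_mask)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(snr_obs), dtype=np.int64)
    for _ in range(n_permutations):
        perm_mask = np.zeros(len(labels), dtype=bool)
        perm_mask[rng.choice(len(labels), size=int(target_mask.sum()), replace=False)] = True
        exceed += _snr(values, perm_mask) <= snr_obs
    p = (1 + exceed) / (1 + n_permutations)

    gene_ids = np.array(matrix.gene_ids)
    order = np.lexsort((gene_ids, snr_obs))
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)

    table = pd.DataFrame(
        {"snr": snr_obs, "rank": rank, "p_value": p}, index=matrix.scores.index
    )
    return SelectivityResult(
        table=table,
        target_lineage=target_lineage,
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class DrugResponseTable:
    """Per-line IC50 values with lineage labels (consistent units)."""

    table: pd.DataFrame  # columns: line, lineage, ic50

    def __post_init__(self) -> None:
        required = {"line", "lineage", "ic50"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"drug table needs columns {sorted(required)}")
        if (self.table["ic50"] <= 0).any():
            raise ValueError("IC50 values must be positive")


def drug_sensitivity_test(
    drug_table: DrugResponseTable,
    target_lineage: str,
    alternative: str = "less",
) -> EnrichmentResult:
    """Mann-Whitney comparison of IC50 between target lineage and the rest.

    The default alternative 'less' asks whether the target lineage is
    more sensitive (lower IC50). Summaries report geometric means, since
    IC50s live on a multiplicative scale.
    """
    df = drug_table.table
    x = df.loc[df["lineage"] == target_lineage, "ic50"].to_numpy(dtype=float)
    y = df.loc[df["lineage"] != target_lineage, "ic50"].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both lineage groups must be non-empty")
    result = mann_whitney(x, y, alternative=alternative)
    details = dict(result.details)
    details.update(
        {
            "geomean_target": float(np.exp(np.mean(np.log(x)))),
            "geomean_other": float(np.exp(np.mean(np.log(y)))),
            "target_lineage": target_lineage,
            "alternative": alternative,
        }
    )
    return EnrichmentResult(
        name="drug_sensitivity_mann_whitney",
        p_value=result.p_value,
        statistic=result.statistic,
        details=details,
    )


VENN_REGIONS = (
    "se_only",
    "dependency_only",
    "drug_only",
    "se_dependency",
    "se_drug",
    "dependency_drug",
    "se_dependency_drug",
)


def integrate_hits(
    se_genes: Iterable[str],
    dependency_hits: Iterable[str],
    drug_validated: Iterable[str],
) -> Dict[str, List[str]]:
    """All seven disjoint regions of the three-screen Venn diagram.

    The triple intersection holds the genes nominated by every screen.
    Output lists are sorted for deterministic reporting.
    """
    a, b, c = set(se_genes), set(dependency_hits), set(drug_validated)
    return {
        "se_only": sorted(a - b - c),
        "dependency_only": sorted(b - a - c),
        "drug_only": sorted(c - a - b),
        "se_dependency": sorted((a & b) - c),
        "se_drug": sorted((a & c) - b),
        "dependency_drug": sorted((b & c) - a),
        "se_dependency_drug": sorted(a & b & c),
    }
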