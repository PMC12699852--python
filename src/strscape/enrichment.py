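"""Observed-vs-expected STR enrichment and group-comparison statistics.

The central score is FE(O, E) = (O - E) / (O + E), where O and E are the
merged STR base-pair totals of a genome and of its dinucleotide-preserving
shuffle.  FE is bounded in [-1, 1]: 1 is maximal enrichment, -1 maximal
depletion, and a genome with no STRs in either version scores 0 by
convention (neither enriched nor depleted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "GroupComparison",
    "fold_enrichment",
    "hedges_g",
    "bh_adjust",
    "compare_real_vs_shuffled",
]


@dataclass(frozen=True)
class EnrichmentResult:
    genome_id: str
    observed_bp: float
    expected_bp: float
    fe: float


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    t_stat: float
    p_raw: float
    p_adj: float
    hedges_g: float


def fold_enrichment(observed_bp: float, expected_bp: float) -> float:
    """FE = (O - E) / (O + E); defined as 0 when O = E = 0."""
    if observed_bp < 0 or expected_bp < 0:
        raise ValueError("counts must be non-negative")
    total = observed_bp + expected_bp
    if total == 0:
        return 0.0
    return (observed_bp - expected_bp) / total


def hedges_g(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Hedges' g: pooled-SD standardized mean difference with the
    small-sample correction J = 1 - 3 / (4(na + nb) - 9)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 values")
    diff = a.mean() - b.mean()
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        return math.copysign(math.inf, diff)
    return j * diff / math.sqrt(pooled_var)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_real_vs_shuffled(
    real: dict[str, float],
    shuffled: dict[str, float],
    equal_var: bool = True,
) -> tuple[GroupComparison, list[EnrichmentResult]]:
    """Compare STR base-pair totals of real genomes against their matched
    shuffles.

    ``real`` and ``shuffled`` map genome_id to merged STR bp (matching is
    by id).  Returns a two-sided independent t-test on the two groups
    (equal-variance by default; set ``equal_var=False`` for Welch),
    Hedges' g, and a per-genome FE list.  With fewer than 2 genomes the
    group statistics are undefined (NaN).
    """
    if set(real) != set(shuffled):
        raise ValueError("real and shuffled genome ids must match")
    ids = sorted(real)
    per_genome = [
        EnrichmentResult(g, real[g], shuffled[g], fold_enrichment(real[g], shuffled[g]))
        for g in ids
    ]
    obs = np.array([real[g] for g in ids], dtype=float)
    exp = np.array([shuffled[g] for g in ids], dtype=float)
    if len(ids) < 2:
        comp = GroupComparison("real", "shuffled", math.nan, math.nan, math.nan, math.nan)
        return comp, per_genome
    t_stat, p_raw = stats.ttest_ind(obs, exp, equal_var=equal_var)
    g = hedges_g(obs, exp)
    comp = GroupComparison("real", "shuffled", float(t_stat), float(p_raw), float(p_raw), g)
    return comp, per_genome
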