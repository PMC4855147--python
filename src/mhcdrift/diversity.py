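"""Temporal genetic-diversity statistics.

Compares the pre-isolation (mainland) and post-isolation (island) strata
locus by locus: observed heterozygosity H_O, unbiased expected
heterozygosity H_E = n/(n-1) (1 - sum p_i^2) over n gene copies, allele
counts N_A, alleles unique to one period, hypergeometric rarefaction of
allelic richness to a standardized number of gene copies, a 2x2 chi-square
test on heterozygote counts, and percent-decline summaries across loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import ISLAND, MAINLAND, GenotypeMatrix, TemporalAssignment


@dataclass
class LocusDiversity:
    locus_id: str
    period: str
    n_samples: int
    n_het: int
    h_obs: float
    h_exp: float
    n_alleles: int
    unique_alleles: int


@dataclass
class HetTestResult:
    locus_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (het, hom) x (a, b)
    chi2: float
    p: float


@dataclass
class TemporalSummary:
    per_locus: pd.DataFrame
    means: pd.DataFrame
    decline_pct: dict[str, int]


def _period_samples(matrix: GenotypeMatrix, period: str, rule: TemporalAssignment | None):
    periods = matrix.periods(rule)
    return [sid for sid, p in periods.items() if p == period]


def heterozygote_counts(
    matrix: GenotypeMatrix, locus: str, sample_ids: list[str]
) -> tuple[int, int]:
    """(n_heterozygous, n_typed) over the given samples at a locus."""
    het = typed = 0
    for sid in sample_ids:
        g = matrix.genotype(sid, locus)
        if g is None:
            continue
        typed += 1
        het += len(g) == 2
    return het, typed


def observed_heterozygosity(
    matrix: GenotypeMatrix, locus: str, period: str,
    rule: TemporalAssignment | None = None,
) -> float:
    het, typed = heterozygote_counts(matrix, locus, _period_samples(matrix, period, rule))
    if typed == 0:
        raise ValueError(f"no genotypes for locus {locus} in period {period}")
    return het / typed


def expected_heterozygosity_from_counts(
    counts: dict[str, int] | list[int], unbiased: bool = True
) -> float:
    values = list(counts.values()) if isinstance(counts, dict) else list(counts)
    n = sum(values)
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    p2 = sum((c / n) ** 2 for c in values)
    h = 1.0 - p2
    return h * n / (n - 1) if unbiased else h


def expected_heterozygosity(
    matrix: GenotypeMatrix, locus: str, period: str,
    rule: TemporalAssignment | None = None, unbiased: bool = True,
) -> float:
    counts = matrix.allele_counts(locus, _period_samples(matrix, period, rule))
    if not counts:
        raise ValueError(f"no genotypes for locus {locus} in period {period}")
    return expected_heterozygosity_from_counts(counts, unbiased)


def rarefied_allele_richness(allele_copy_counts: dict[str, int] | list[int], g: int) -> float:
    """Expected distinct alleles in a subsample of ``g`` gene copies.

    Hypergeometric expectation without replacement:
    sum_j [1 - C(N - N_j, g) / C(N, g)] for allele copy counts N_j summing
    to N.  At g = N this equals the observed allele count.
    """
    values = (
        list(allele_copy_counts.values())
        if isinstance(allele_copy_counts, dict)
        else list(allele_copy_counts)
    )
    n_total = sum(values)
    if not 1 <= g <= n_total:
        raise ValueError(f"subsample size g={g} outside [1, {n_total}]")
    denom = math.comb(n_total, g)
    return sum(1.0 - math.comb(n_total - nj, g) / denom for nj in values)


def rarefaction_curve(
    allele_copy_counts: dict[str, int] | list[int], g_max: int = 24
) -> list[tuple[int, float]]:
    values = (
        list(allele_copy_counts.values())
        if isinstance(allele_copy_counts, dict)
        else list(allele_copy_counts)
    )
    top = min(g_max, sum(values))
    return [(g, rarefied_allele_richness(values, g)) for g in range(1, top + 1)]


def het_chi_square(
    het_a: int, hom_a: int, het_b: int, hom_b: int,
    locus_id: str = "", correction: bool = False,
) -> HetTestResult:
    """Pearson chi-square on the 2x2 heterozygote/homozygote x period table.

    No continuity correction by default.  p comes from the chi-square
    distribution with 1 degree of freedom.
    """
    table = np.array([[het_a, het_b], [hom_a, hom_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return HetTestResult(
        locus_id, ((het_a, hom_a), (het_b, hom_b)), float(chi2), float(p)
    )


def het_test_for_locus(
    matrix: GenotypeMatrix, locus: str, rule: TemporalAssignment | None = None
) -> HetTestResult:
    het_m, n_m = heterozygote_counts(matrix, locus, _period_samples(matrix, MAINLAND, rule))
    het_i, n_i = heterozygote_counts(matrix, locus, _period_samples(matrix, ISLAND, rule))
    return het_chi_square(het_m, n_m - het_m, het_i, n_i - het_i, locus_id=locus)


def mean_decline_pct(mainland_values: list[float], island_values: list[float]) -> int:
    """Percent decline of across-locus means, rounded to nearest integer."""
    m = float(np.mean(mainland_values))
    i = float(np.mean(island_values))
    if m == 0:
        raise ValueError("mainland mean is zero; decline undefined")
    return round(100.0 * (m - i) / m)


def het_counts_from_ho(ho_values: list[float], n: int = 12) -> list[int]:
    """Convert printed H_O values back to heterozygote counts (round(H_O*n))."""
    return [round(h * n) for h in ho_values]


def locus_diversity(
    matrix: GenotypeMatrix, locus: str, period: str,
    rule: TemporalAssignment | None = None, unbiased: bool = True,
) -> LocusDiversity:
    other = ISLAND if period == MAINLAND else MAINLAND
    own = _period_samples(matrix, period, rule)
    het, typed = heterozygote_counts(matrix, locus, own)
    counts = matrix.allele_counts(locus, own)
    other_alleles = set(matrix.allele_counts(locus, _period_samples(matrix, other, rule)))
    if typed == 0:
        raise ValueError(f"no genotypes for locus {locus} in period {period}")
    return LocusDiversity(
        locus_id=locus,
        period=period,
        n_samples=typed,
        n_het=het,
        h_obs=het / typed,
        h_exp=expected_heterozygosity_from_counts(counts, unbiased),
        n_alleles=len(counts),
        unique_alleles=len(set(counts) - other_alleles),
    )


def temporal_summary(
    matrix: GenotypeMatrix,
    rule: TemporalAssignment | None = None,
    unbiased: bool = True,
) -> TemporalSummary:
    """Per-locus diversity by period, across-locus means +- SD, and declines.

    Percent decline is 100 (mean_mainland - mean_island) / mean_mainland,
    rounded to the nearest integer, computed on the exact count-derived
    values (not on rounded table entries).
    """
    rows = []
    for locus in matrix.loci():
        for period in (MAINLAND, ISLAND):
            d = locus_diversity(matrix, locus, period, rule, unbiased)
            rows.append(vars(d))
    per_locus = pd.DataFrame(rows)
    if per_locus.empty or per_locus["period"].nunique() < 2:
        raise ValueError("both temporal periods must be populated")
    stats_cols = ["h_obs", "h_exp", "n_alleles"]
    means = per_locus.groupby("period")[stats_cols].agg(["mean", "std"])
    decline = {
        col: mean_decline_pct(
            per_locus.loc[per_locus.period == MAINLAND, col].tolist(),
            per_locus.loc[per_locus.period == ISLAND, col].tolist(),
        )
        for col in stats_cols
    }
    return TemporalSummary(per_locus=per_locus, means=means, decline_pct=decline)
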