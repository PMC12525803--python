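"""Exact test of Hardy–Weinberg proportions (Levene–Haldane).

Conditional on the observed allele counts ``(nA, 2n − nA)`` at a
biallelic locus in a sample of ``n`` diploids, the number of
heterozygotes ``h`` under random union of gametes has probability

    P(h) = 2^h · n! / (n1! · h! · n2!) · nA! · (2n − nA)! / (2n)!

where ``n1 = (nA − h)/2`` and ``n2 = (2n − nA − h)/2`` are the two
homozygote counts; ``h`` ranges over values of the same parity as
``nA`` with ``0 ≤ h ≤ min(nA, 2n − nA)``.  The two-sided exact p-value
sums ``P(h')`` over all configurations no more probable than the
observed one (ties included).  Monomorphic samples give p = 1.

All arithmetic is done with log-factorials so the test is stable at
sample sizes far beyond the panel sizes it is used on here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .dart_io import SNPDataset

#: relative tolerance for probability ties when summing the tail
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class HWEResult:
    """Exact-test outcome for one locus in one population."""

    locus: str
    population: str
    n_hom1: int
    n_het: int
    n_hom2: int
    n: int
    p_value: float


def _log_factorial(x: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(x, dtype=float) + 1.0)


@lru_cache(maxsize=65536)
def het_count_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the heterozygote count.

    Returns the admissible heterozygote counts and their probabilities
    given ``n`` diploids and ``n_a`` copies of one allele (either allele
    works; the distribution depends on ``n_a`` only through
    ``min(n_a, 2n − n_a)`` by symmetry).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= n_a <= 2 * n:
        raise ValueError("allele count outside [0, 2n]")
    h_max = min(n_a, 2 * n - n_a)
    hs = np.arange(h_max % 2, h_max + 1, 2)
    n1 = (n_a - hs) // 2
    n2 = (2 * n - n_a - hs) // 2
    log_p = (
        hs * np.log(2.0)
        + _log_factorial(n)
        - _log_factorial(n1)
        - _log_factorial(hs)
        - _log_factorial(n2)
        + _log_factorial(n_a)
        + _log_factorial(2 * n - n_a)
        - _log_factorial(2 * n)
    )
    probs = np.exp(log_p)
    return hs, probs


def hwe_exact(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value for one genotype triple.

    Parameters are the counts of the two homozygote classes and the
    heterozygotes; which allele is "reference" is irrelevant
    (``hwe_exact(a, h, b) == hwe_exact(b, h, a)``).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one called genotype is required")
    n_a = 2 * n_hom1 + n_het
    hs, probs = het_count_distribution(n, n_a)
    p_obs = probs[np.searchsorted(hs, n_het)]
    p = probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


def hwe_screen(
    ds: SNPDataset,
    by_population: bool = True,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[HWEResult]:
    """Genome screen for significant departures from HW proportions.

    Tests every locus within each population (or the pooled panel when
    ``by_population`` is false), skipping loci with fewer than 2 called
    genotypes or monomorphic within the group.  Returns results with
    ``p ≤ alpha`` sorted by p-value; ``bonferroni`` divides alpha by the
    number of tests performed (off by default — a raw screen).
    """
    results = hwe_test_all(ds, by_population=by_population)
    cut = alpha / len(results) if (bonferroni and results) else alpha
    hits = [r for r in results if r.p_value <= cut]
    return sorted(hits, key=lambda r: (r.p_value, r.population, r.locus))


def hwe_test_all(ds: SNPDataset, by_population: bool = True) -> list[HWEResult]:
    """Exact-test every testable locus×group combination (no alpha cut)."""
    groups = ds.populations if by_population else ["all"]
    out: list[HWEResult] = []
    loc_ids = [loc.id for loc in ds.loci]
    for pop in groups:
        rows = ds.population_indices(pop) if by_population else np.arange(ds.n_individuals)
        g = ds.genotypes[rows]
        n0 = (g == 0).sum(axis=0)
        n1 = (g == 1).sum(axis=0)
        n2 = (g == 2).sum(axis=0)
        n = n0 + n1 + n2
        n_a = 2 * n0 + n1
        testable = (n >= 2) & (n_a > 0) & (n_a < 2 * n)
        for j in np.flatnonzero(testable):
            out.append(
                HWEResult(
                    locus=loc_ids[j],
                    population=pop,
                    n_hom1=int(n0[j]),
                    n_het=int(n1[j]),
                    n_hom2=int(n2[j]),
                    n=int(n[j]),
                    p_value=hwe_exact(int(n0[j]), int(n1[j]), int(n2[j])),
                )
            )
    return out
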