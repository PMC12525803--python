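"""Pairwise population accounting of fixed differences and private alleles.

For a pair of populations, over the loci at which both have at least one
called genotype ("shared" loci), with ``p1``/``p2`` the reference-allele
frequencies:

* fixed differences — loci with ``|p1 − p2| ≥ 1 − fixed_tolerance``
  (strict fixation for different alleles at the default tolerance 0);
* private alleles — each allele (reference or alternate) counted for a
  population when present there and absent from the partner;
* AFD — the mean of ``|p1 − p2|`` over shared loci;
* Chao1-corrected private-allele richness — ``S_priv + f1(f1−1)/(2(f2+1))``
  where ``f1``/``f2`` are private alleles observed as exactly one / two
  allele copies in that population, a singleton/doubleton correction for
  private alleles that the sample missed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dart_io import SNPDataset


@dataclass(frozen=True)
class PairSharingReport:
    """Fixed/private/AFD/Chao accounting for one unordered population pair."""

    pop1: str
    pop2: str
    n_shared_loci: int
    fixed: int
    priv1: int
    priv2: int
    chao1: float
    chao2: float
    afd: float

    @property
    def totalpriv(self) -> int:
        return self.priv1 + self.priv2


def _pop_counts(ds: SNPDataset, pop: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ref allele copies, alt allele copies, called genotypes) per locus."""
    g = ds.genotypes[ds.population_indices(pop)]
    n0 = (g == 0).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    return 2 * n0 + n1, 2 * n2 + n1, n0 + n1 + n2


def _chao_correction(s_priv: int, copies: np.ndarray) -> float:
    """Chao1 estimate from the copy counts of one population's private alleles."""
    f1 = int((copies == 1).sum())
    f2 = int((copies == 2).sum())
    return s_priv + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def pair_sharing(
    ds: SNPDataset, pop1: str, pop2: str, fixed_tolerance: float = 0.0
) -> PairSharingReport:
    """Fixed-difference / private-allele report for one population pair."""
    ref1, alt1, n1 = _pop_counts(ds, pop1)
    ref2, alt2, n2 = _pop_counts(ds, pop2)
    shared = (n1 >= 1) & (n2 >= 1)
    if not shared.any():
        raise ValueError(f"populations {pop1!r} and {pop2!r} share no called loci")
    ref1, alt1, n1 = ref1[shared], alt1[shared], n1[shared]
    ref2, alt2, n2 = ref2[shared], alt2[shared], n2[shared]
    p1 = ref1 / (2.0 * n1)
    p2 = ref2 / (2.0 * n2)

    diff = np.abs(p1 - p2)
    fixed = int((diff >= 1.0 - fixed_tolerance - 1e-12).sum())
    afd = float(diff.mean())

    # private-allele masks per allele per locus
    ref_priv1 = (ref1 > 0) & (ref2 == 0)
    alt_priv1 = (alt1 > 0) & (alt2 == 0)
    ref_priv2 = (ref2 > 0) & (ref1 == 0)
    alt_priv2 = (alt2 > 0) & (alt1 == 0)
    priv1 = int(ref_priv1.sum() + alt_priv1.sum())
    priv2 = int(ref_priv2.sum() + alt_priv2.sum())

    copies1 = np.concatenate([ref1[ref_priv1], alt1[alt_priv1]])
    copies2 = np.concatenate([ref2[ref_priv2], alt2[alt_priv2]])
    return PairSharingReport(
        pop1=pop1,
        pop2=pop2,
        n_shared_loci=int(shared.sum()),
        fixed=fixed,
        priv1=priv1,
        priv2=priv2,
        chao1=_chao_correction(priv1, copies1),
        chao2=_chao_correction(priv2, copies2),
        afd=afd,
    )


def sharing_matrix(ds: SNPDataset, fixed_tolerance: float = 0.0) -> list[PairSharingReport]:
    """`pair_sharing` for every unordered pair, in population order."""
    pops = ds.populations
    return [
        pair_sharing(ds, pops[i], pops[j], fixed_tolerance=fixed_tolerance)
        for i in range(len(pops))
        for j in range(i + 1, len(pops))
    ]
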