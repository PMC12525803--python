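"""Hierarchical AMOVA and PCA of the genotype matrix.

AMOVA partitions the total molecular variance among three nested
levels — among populations, among individuals within populations, and
within individuals — from squared Euclidean distances between allele
vectors.  Each diploid individual contributes two pseudo-haploid allele
rows (genotype code 0 → alleles (0,0), 1 → (0,1), 2 → (1,1)); for
biallelic SNPs this squared-Euclidean allelic distance is the standard
AMOVA distance up to scaling.  Missing genotypes make both allele
entries missing, and pairwise distances are rescaled by the number of
loci actually compared.

Variance components follow the nested ANOVA expectations with the
unequal-sample-size coefficient; Phi statistics are

* ``Phi_ST`` — among-population differentiation,
* ``Phi_IS`` — inbreeding of individuals within populations,
* ``Phi_IT`` — total inbreeding.

Significance is by permutation: whole individuals relabeled across
populations (among-population component), allele rows re-paired within
populations (among-individual component), and allele rows re-paired
across the whole panel (total, tested on Phi_IT).

PCA mean-imputes missing dosages per locus, column-centers, and runs a
singular value decomposition; axis signs are fixed by forcing the
largest-magnitude loading of each axis positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dart_io import MISSING, SNPDataset

logger = logging.getLogger(__name__)

_LEVELS = ("among_populations", "among_individuals", "within_individuals")


@dataclass
class AMOVAResult:
    sigma2: dict[str, float]          # raw variance components (may be negative)
    percent: dict[str, float]         # negative components floored at 0, sums to 100
    df: dict[str, int]
    ss: dict[str, float]
    phi_st: float
    phi_is: float
    phi_it: float
    p_values: dict[str, float]
    n_permutations: int


@dataclass
class PCAResult:
    scores: pd.DataFrame              # individuals × axes
    explained_percent: np.ndarray     # per axis, nonincreasing
    loadings: np.ndarray              # axes × loci


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

_ALLELE_ROWS = {0: (0.0, 0.0), 1: (0.0, 1.0), 2: (1.0, 1.0), MISSING: (np.nan, np.nan)}


def _allele_matrix(g: np.ndarray) -> np.ndarray:
    """(2N, L) alt-allele indicator rows, two per individual, NaN missing."""
    n, L = g.shape
    out = np.empty((2 * n, L))
    first = np.where(g == 1, 0.0, np.where(g == 2, 1.0, 0.0))
    second = np.where(g >= 1, 1.0, 0.0)
    miss = g == MISSING
    first[miss] = np.nan
    second[miss] = np.nan
    out[0::2] = first
    out[1::2] = second
    return out


def _squared_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances rescaled by loci compared."""
    m, L = X.shape
    D2 = np.zeros((m, m))
    for j in range(m - 1):
        diff = X[j + 1 :] - X[j]
        cnt = (~np.isnan(diff)).sum(axis=1)
        sq = np.nansum(diff**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(cnt > 0, L * sq / cnt, 0.0)
        D2[j, j + 1 :] = d
        D2[j + 1 :, j] = d
    return D2


def _ss(D2: np.ndarray, groups: list[np.ndarray]) -> float:
    total = 0.0
    for g in groups:
        total += D2[np.ix_(g, g)].sum() / (2.0 * g.size)
    return total


def _components(
    D2: np.ndarray, pop_of_ind: np.ndarray, pairing: np.ndarray
) -> tuple[float, float, float, dict[str, float], dict[str, int]]:
    """Raw variance components given individual→pop labels and allele-row pairing.

    ``pairing`` is a (N, 2) array of allele-row indices per individual.
    """
    n_ind = pop_of_ind.size
    pops, counts = np.unique(pop_of_ind, return_counts=True)
    n_pops = pops.size
    all_rows = pairing.ravel()
    ss_total = _ss(D2, [all_rows])
    pop_groups = [pairing[pop_of_ind == p].ravel() for p in pops]
    ss_wp = _ss(D2, pop_groups)
    ss_wi = _ss(D2, [pairing[i] for i in range(n_ind)])
    ss_ai = ss_wp - ss_wi
    ss_ap = ss_total - ss_wp

    df_ap = n_pops - 1
    df_ai = n_ind - n_pops
    df_wi = n_ind
    c = 2 * counts  # allele copies per population
    t = c.sum()
    n_c = (t - (c**2).sum() / t) / df_ap

    sigma_w = ss_wi / df_wi
    ms_ai = ss_ai / df_ai if df_ai > 0 else np.nan
    sigma_ind = (ms_ai - sigma_w) / 2.0
    ms_ap = ss_ap / df_ap
    sigma_pop = (ms_ap - sigma_w - 2.0 * sigma_ind) / n_c
    ss = {"among_populations": ss_ap, "among_individuals": ss_ai, "within_individuals": ss_wi}
    df = {"among_populations": df_ap, "among_individuals": df_ai, "within_individuals": df_wi}
    return sigma_pop, sigma_ind, sigma_w, ss, df


def amova(ds: SNPDataset, n_perm: int = 999, seed: int | None = None) -> AMOVAResult:
    """Two-level hierarchical AMOVA with permutation significance.

    Populations of size 1 are excluded (a single individual carries no
    among-individual information) with a warning.  Requires at least two
    populations of size ≥ 2 afterwards.
    """
    sizes = {p: len(ds.population_indices(p)) for p in ds.populations}
    singletons = [p for p, n in sizes.items() if n < 2]
    if singletons:
        logger.warning("amova: excluding single-individual populations: %s", singletons)
        keep = np.array([ind.population not in singletons for ind in ds.individuals])
        ds = ds.subset(individuals=keep)
    pops = ds.populations
    if len(pops) < 2:
        raise ValueError("amova needs >= 2 populations with >= 2 individuals each")

    rng = np.random.default_rng(seed)
    X = _allele_matrix(ds.genotypes)
    D2 = _squared_distances(X)
    n_ind = ds.n_individuals
    pop_lut = {p: k for k, p in enumerate(pops)}
    pop_of_ind = np.array([pop_lut[ind.population] for ind in ds.individuals])
    pairing = np.arange(2 * n_ind).reshape(n_ind, 2)

    s_pop, s_ind, s_w, ss, df = _components(D2, pop_of_ind, pairing)
    total = s_pop + s_ind + s_w
    phi_st = s_pop / total
    phi_is = s_ind / (s_ind + s_w)
    phi_it = (s_pop + s_ind) / total

    floored = np.maximum([s_pop, s_ind, s_w], 0.0)
    percent = 100.0 * floored / floored.sum()

    # permutation nulls
    exceed = dict.fromkeys(_LEVELS, 0)
    for _ in range(n_perm):
        # among populations: relabel whole individuals
        perm_pops = rng.permutation(pop_of_ind)
        sp, _, _, _, _ = _components(D2, perm_pops, pairing)
        exceed["among_populations"] += sp >= s_pop
        # among individuals within pops: re-pair allele rows within each pop
        pairing_w = pairing.copy()
        for k in range(len(pops)):
            rows = pairing[pop_of_ind == k].ravel()
            pairing_w[pop_of_ind == k] = rng.permutation(rows).reshape(-1, 2)
        _, si, _, _, _ = _components(D2, pop_of_ind, pairing_w)
        exceed["among_individuals"] += si >= s_ind
        # total inbreeding: re-pair allele rows across the whole panel
        pairing_t = rng.permutation(pairing.ravel()).reshape(n_ind, 2)
        spt, sit, swt, _, _ = _components(D2, pop_of_ind, pairing_t)
        tot = spt + sit + swt
        phi_it_perm = (spt + sit) / tot if tot > 0 else 0.0
        exceed["within_individuals"] += phi_it_perm >= phi_it
    p_values = {k: (1 + v) / (n_perm + 1) for k, v in exceed.items()}

    return AMOVAResult(
        sigma2=dict(zip(_LEVELS, (s_pop, s_ind, s_w))),
        percent=dict(zip(_LEVELS, percent)),
        df=df,
        ss=ss,
        phi_st=float(phi_st),
        phi_is=float(phi_is),
        phi_it=float(phi_it),
        p_values=p_values,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(ds: SNPDataset, n_axes: int = 10) -> PCAResult:
    """Principal component analysis of mean-imputed, centered dosages."""
    if ds.n_individuals < 2:
        raise ValueError("pca needs >= 2 individuals")
    d = ds.dosages()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing loci
    miss = np.isnan(d)
    d[miss] = np.take(col_mean, np.nonzero(miss)[1])
    d -= d.mean(axis=0)
    if not np.any(d):
        raise ValueError("pca: genotype matrix has zero variance")
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    k = min(n_axes, s.size)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    for a in range(k):  # deterministic sign: largest |loading| positive
        j = np.argmax(np.abs(loadings[a]))
        if loadings[a, j] < 0:
            loadings[a] *= -1.0
            scores[:, a] *= -1.0
    explained = 100.0 * (s**2) / (s**2).sum()
    frame = pd.DataFrame(
        scores,
        index=[ind.id for ind in ds.individuals],
        columns=[f"PC{a + 1}" for a in range(k)],
    )
    return PCAResult(scores=frame, explained_percent=explained[:k], loadings=loadings)
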