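"""Linkage disequilibrium: pairwise r², permutation p-values, decay curves.

r² is the squared Pearson correlation of genotype dosages (codes 0/1/2)
over pairwise-complete individuals — the "composite" LD estimator, which
needs no phasing and is the robust choice for unphased, highly selfed
diploids.  Heterozygotes are retained as dosage 1.  Significance comes
from a permutation test (one locus's genotype vector shuffled), with the
add-one estimator ``p = (1 + #{r²* ≥ r²}) / (n_perm + 1)`` so p is never
zero.  Per-chromosome summaries add a lowess (locally weighted
first-degree polynomial) decay fit of r² against physical distance and
the first grid distance at which the fit drops below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dart_io import SNPDataset

#: p-value cutoff used for the "proportion significant" summary
SIGNIFICANCE_LEVEL = 0.001


@dataclass(frozen=True)
class LDPair:
    locus_a: str
    locus_b: str
    chromosome_a: str | None
    chromosome_b: str | None
    distance: float | None  # bp; None for inter-chromosomal pairs
    r2: float
    p_value: float
    n_used: int


@dataclass
class LDSummary:
    chromosome: str
    n_pairs: int
    mean_r2: float
    prop_significant: float
    mean_r2_unlinked: float | None
    decay_distance: np.ndarray | None
    decay_r2: np.ndarray | None
    d_crossing: float | None
    low_confidence: bool


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation; None when either vector is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return None
    return float((xc @ yc) ** 2 / (sx * sy))


def _permutation_p(x: np.ndarray, y: np.ndarray, r2_obs: float, n_perm: int, rng) -> float:
    n = x.size
    idx = np.tile(np.arange(n), (n_perm, 1))
    idx = rng.permuted(idx, axis=1)
    yp = y[idx]  # (n_perm, n)
    xc = x - x.mean()
    ypc = yp - yp.mean(axis=1, keepdims=True)
    num = (ypc @ xc) ** 2
    den = float(xc @ xc) * (ypc**2).sum(axis=1)
    r2_perm = np.where(den > 0, num / den, 0.0)
    return float((1 + (r2_perm >= r2_obs - 1e-15).sum()) / (n_perm + 1))


def _candidate_pairs(ds: SNPDataset, scope: str, max_pairs: int, rng) -> list[tuple[int, int]]:
    chrom = np.array(
        [str(l.chromosome) if l.chromosome is not None else "" for l in ds.loci]
    )
    if scope == "within":
        pairs: list[tuple[int, int]] = []
        for c in np.unique(chrom[chrom != ""]):
            idx = np.flatnonzero(chrom == c)
            a, b = np.triu_indices(idx.size, k=1)
            pairs.extend(zip(idx[a].tolist(), idx[b].tolist()))
        if len(pairs) > max_pairs:
            sel = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[k] for k in np.sort(sel)]
        return pairs
    if scope == "between":
        mapped = np.flatnonzero(chrom != "")
        pairs = []
        seen: set[tuple[int, int]] = set()
        attempts = 0
        while len(pairs) < max_pairs and attempts < 50 * max_pairs:
            i, j = rng.choice(mapped, size=2, replace=False)
            attempts += 1
            if chrom[i] == chrom[j]:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(key)
        return pairs
    raise ValueError("scope must be 'within' or 'between'")


def ld_pairs(
    ds: SNPDataset,
    scope: str = "within",
    max_pairs: int = 2_000_000,
    n_perm: int = 1000,
    seed: int | None = None,
    min_n: int = 4,
) -> list[LDPair]:
    """Pairwise composite r² with permutation p-values.

    ``scope='within'`` enumerates all same-chromosome pairs (uniformly
    subsampled with ``seed`` when they exceed ``max_pairs``);
    ``scope='between'`` samples up to ``max_pairs`` cross-chromosome
    pairs as an unlinked baseline.  Pairs with fewer than ``min_n``
    pairwise-complete individuals, or with a constant dosage vector, are
    skipped.  The input is expected to be MAF-filtered already.
    """
    rng = np.random.default_rng(seed)
    dos = ds.dosages()
    out: list[LDPair] = []
    n_skipped = 0
    for i, j in _candidate_pairs(ds, scope, max_pairs, rng):
        xi, xj = dos[:, i], dos[:, j]
        mask = ~np.isnan(xi) & ~np.isnan(xj)
        n_used = int(mask.sum())
        if n_used < min_n:
            n_skipped += 1
            continue
        r2 = _pair_r2(xi[mask], xj[mask])
        if r2 is None:
            n_skipped += 1
            continue
        p = _permutation_p(xi[mask], xj[mask], r2, n_perm, rng)
        la, lb = ds.loci[i], ds.loci[j]
        same_chrom = la.chromosome == lb.chromosome and la.mapped and lb.mapped
        out.append(
            LDPair(
                locus_a=la.id,
                locus_b=lb.id,
                chromosome_a=str(la.chromosome) if la.chromosome is not None else None,
                chromosome_b=str(lb.chromosome) if lb.chromosome is not None else None,
                distance=float(abs(la.position - lb.position)) if same_chrom else None,
                r2=r2,
                p_value=p,
                n_used=n_used,
            )
        )
    if n_skipped:
        ds.log(f"ld_pairs(scope={scope}): skipped {n_skipped} pairs (n_used < {min_n} or constant dosage)")
    return out


def _decay_fit(
    dist: np.ndarray, r2: np.ndarray, span: float, threshold: float, grid_points: int
) -> tuple[np.ndarray, np.ndarray, float | None]:
    fitted = lowess(r2, dist, frac=span, it=0, return_sorted=True)
    grid = np.linspace(dist.min(), dist.max(), grid_points)
    curve = np.interp(grid, fitted[:, 0], fitted[:, 1])
    below = np.flatnonzero(curve < threshold)
    d_crossing = float(grid[below[0]]) if below.size else None
    return grid, curve, d_crossing


def ld_summaries(
    pairs: list[LDPair],
    loess_span: float = 0.3,
    threshold: float = 0.2,
    grid_points: int = 100,
    min_pairs: int = 10,
) -> list[LDSummary]:
    """Per-chromosome LD summaries from a list of computed pairs.

    Within-chromosome pairs (those with a distance) are grouped by
    chromosome; inter-chromosomal pairs contribute a single unlinked
    baseline mean attached to every summary row.  Chromosomes with fewer
    than ``min_pairs`` pairs are flagged low-confidence and get no decay
    fit.
    """
    between = [p.r2 for p in pairs if p.distance is None]
    baseline = float(np.mean(between)) if between else None
    by_chrom: dict[str, list[LDPair]] = {}
    for p in pairs:
        if p.distance is not None:
            by_chrom.setdefault(p.chromosome_a, []).append(p)
    out = []
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        plist = by_chrom[chrom]
        r2 = np.array([p.r2 for p in plist])
        dist = np.array([p.distance for p in plist])
        low_conf = len(plist) < min_pairs
        grid = curve = d_crossing = None
        if not low_conf:
            grid, curve, d_crossing = _decay_fit(dist, r2, loess_span, threshold, grid_points)
        out.append(
            LDSummary(
                chromosome=chrom,
                n_pairs=len(plist),
                mean_r2=float(r2.mean()),
                prop_significant=float(
                    np.mean([p.p_value < SIGNIFICANCE_LEVEL for p in plist])
                ),
                mean_r2_unlinked=baseline,
                decay_distance=grid,
                decay_r2=curve,
                d_crossing=d_crossing,
                low_confidence=low_conf,
            )
        )
    return out
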