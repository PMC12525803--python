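"""Statistical behaviour of the synthetic-panel generator."""

import numpy as np
import pytest

from beanpop import SimulationConfig, simulate_dataset
from beanpop.dart_io import SNPDataset


def test_same_seed_same_dataset():
    cfg = dict(n_pops=2, n_ind=(5, 5), n_loci=50, seed=42, missing_rate=0.1)
    a = simulate_dataset(SimulationConfig(**cfg))
    b = simulate_dataset(SimulationConfig(**cfg))
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    assert [l.id for l in a.loci] == [l.id for l in b.loci]


def test_seed_is_mandatory():
    with pytest.raises(ValueError, match="seed"):
        SimulationConfig(n_pops=1, n_ind=(5,), n_loci=10)


def test_hardy_weinberg_limit_heterozygote_fraction():
    """theta=0, F=0: per-locus het fraction ≈ 2pq within binomial error."""
    ds = simulate_dataset(
        SimulationConfig(
            n_pops=1, n_ind=(2000,), n_loci=60, theta=0.0, inbreeding=0.0,
            missing_rate=0.0, seed=3,
        )
    )
    g = ds.genotypes
    n = g.shape[0]
    p = (2 * (g == 0).sum(0) + (g == 1).sum(0)) / (2 * n)
    het = (g == 1).mean(0)
    expected = 2 * p * (1 - p)
    # 4 SDs of a binomial proportion at n=2000
    tol = 4 * np.sqrt(expected * (1 - expected) / n) + 1e-9
    assert np.all(np.abs(het - expected) < np.maximum(tol, 0.05))


def test_complete_inbreeding_gives_no_heterozygotes():
    for lam in (0.0, 1e6):  # both sampling modes
        ds = simulate_dataset(
            SimulationConfig(
                n_pops=2, n_ind=(20, 20), n_loci=100, inbreeding=1.0,
                missing_rate=0.0, ld_lambda=lam, seed=5,
            )
        )
        assert (ds.genotypes == 1).sum() == 0


def _mean_afd(theta: float, seed: int) -> float:
    ds = simulate_dataset(
        SimulationConfig(
            n_pops=2, n_ind=(30, 30), n_loci=300, theta=theta,
            inbreeding=0.0, missing_rate=0.0, seed=seed,
        )
    )
    g = ds.genotypes
    freqs = []
    for pop in ds.populations:
        sub = g[ds.population_indices(pop)]
        freqs.append((2 * (sub == 0).sum(0) + (sub == 1).sum(0)) / (2 * sub.shape[0]))
    return float(np.abs(freqs[0] - freqs[1]).mean())


def test_allele_frequency_divergence_increases_with_theta():
    afd = {
        theta: np.mean([_mean_afd(theta, s) for s in range(10)])
        for theta in (0.01, 0.05, 0.2)
    }
    assert afd[0.01] < afd[0.05] < afd[0.2]


def test_haplotype_mode_ld_decays_with_distance():
    """Mean r² of close pairs (<0.1λ) exceeds that of distant pairs (>10λ)."""
    lam = 1e6
    ds = simulate_dataset(
        SimulationConfig(
            n_pops=1, n_ind=(50,), n_loci=300, n_chrom=1, chrom_length=20_000_000,
            theta=0.0, inbreeding=0.0, missing_rate=0.0,
            ld_lambda=lam, haplotype_pool=12, seed=9,
        )
    )
    pos = np.array([l.position for l in ds.loci], dtype=float)
    d = ds.genotypes.astype(float)
    corr = np.corrcoef(d.T)
    i, j = np.triu_indices(len(pos), k=1)
    dist = np.abs(pos[i] - pos[j])
    r2 = corr[i, j] ** 2
    ok = np.isfinite(r2)
    close = ok & (dist < 0.1 * lam)
    far = ok & (dist > 10 * lam)
    assert close.sum() > 10 and far.sum() > 10
    assert r2[close].mean() > r2[far].mean()


def test_missingness_rate_is_respected():
    ds = simulate_dataset(
        SimulationConfig(n_pops=1, n_ind=(100,), n_loci=200, missing_rate=0.08, seed=13)
    )
    rate = (ds.genotypes == -1).mean()
    assert 0.06 < rate < 0.10


def test_loci_sorted_within_chromosome():
    ds = simulate_dataset(SimulationConfig(n_pops=1, n_ind=(5,), n_loci=200, seed=1))
    by_chrom = {}
    for loc in ds.loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc.position)
    for positions in by_chrom.values():
        assert positions == sorted(positions)
        assert positions[0] >= 1
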