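"""Composite r², permutation p-values and decay summaries."""

import numpy as np
import pytest

from beanpop import ld_pairs, ld_summaries
from beanpop.ld import LDPair, _pair_r2

from conftest import make_dataset


def _pair_lookup(pairs, id_a, id_b):
    for p in pairs:
        if {p.locus_a, p.locus_b} == {id_a, id_b}:
            return p
    raise KeyError((id_a, id_b))


def test_duplicated_locus_has_r2_one():
    codes = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]])
    ds = make_dataset(codes, ["A"] * 5)
    pairs = ld_pairs(ds, "within", n_perm=99, seed=0)
    assert pairs[0].r2 == pytest.approx(1.0)
    assert pairs[0].n_used == 5


def test_perfect_negative_correlation_squares_to_one():
    codes = np.array([[0, 2], [0, 2], [2, 0], [2, 0]])
    ds = make_dataset(codes, ["A"] * 4)
    pairs = ld_pairs(ds, "within", n_perm=99, seed=0)
    assert pairs[0].r2 == pytest.approx(1.0)


def test_r2_matches_hand_computed_covariance_ratio():
    x = np.array([0, 0, 1, 1, 2, 2, 0, 2], dtype=float)
    y = np.array([0, 1, 1, 0, 2, 2, 0, 2], dtype=float)
    # plain-sum covariance ratio computed independently of the implementation
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    expected = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    ds = make_dataset(np.column_stack([x, y]).astype(np.int8), ["A"] * 8)
    pair = ld_pairs(ds, "within", n_perm=99, seed=1)[0]
    assert pair.r2 == pytest.approx(expected)


def test_r2_invariant_to_allele_relabeling():
    rng = np.random.default_rng(5)
    codes = rng.integers(0, 3, size=(20, 2)).astype(np.int8)
    flipped = codes.copy()
    flipped[:, 1] = 2 - flipped[:, 1]  # swap ref/alt at locus 1
    a = ld_pairs(make_dataset(codes, ["A"] * 20), "within", n_perm=49, seed=2)[0]
    b = ld_pairs(make_dataset(flipped, ["A"] * 20), "within", n_perm=49, seed=2)[0]
    assert a.r2 == pytest.approx(b.r2)


def test_small_overlap_pairs_skipped():
    codes = np.array([[0, -1], [2, -1], [1, -1], [-1, 0], [-1, 2], [-1, 1]])
    ds = make_dataset(codes, ["A"] * 6)
    assert ld_pairs(ds, "within", n_perm=9, seed=0, min_n=4) == []


def test_between_scope_pairs_cross_chromosomes():
    rng = np.random.default_rng(6)
    codes = rng.integers(0, 3, size=(15, 10)).astype(np.int8)
    ds = make_dataset(codes, ["A"] * 15, chromosomes=[1] * 5 + [2] * 5,
                      positions=list(range(1, 11)))
    pairs = ld_pairs(ds, "between", max_pairs=12, n_perm=19, seed=3)
    assert 0 < len(pairs) <= 12
    assert all(p.distance is None for p in pairs)
    assert all(p.chromosome_a != p.chromosome_b for p in pairs)


def test_constant_r2_series_has_flat_fit_and_no_crossing():
    pairs = [
        LDPair("a", "b", "1", "1", float(d), 0.5, 0.5, 20)
        for d in range(1000, 21000, 1000)
    ]
    (summary,) = ld_summaries(pairs, threshold=0.2)
    assert summary.mean_r2 == pytest.approx(0.5)
    assert np.allclose(summary.decay_r2, 0.5)
    assert summary.d_crossing is None
    assert not summary.low_confidence


def test_sparse_chromosome_flagged_low_confidence():
    pairs = [LDPair("a", "b", "7", "7", 1000.0, 0.3, 0.2, 20)]
    (summary,) = ld_summaries(pairs, min_pairs=10)
    assert summary.low_confidence
    assert summary.decay_r2 is None


def test_unlinked_baseline_attached_to_summaries():
    within = [
        LDPair("a", "b", "1", "1", float(d), 0.4, 0.01, 20) for d in range(1, 15)
    ]
    between = [LDPair("c", "d", "1", "2", None, 0.1, 0.5, 20)] * 5
    (summary,) = ld_summaries(within + between)
    assert summary.mean_r2_unlinked == pytest.approx(0.1)
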