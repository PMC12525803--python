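"""Per-locus index arithmetic and density binning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beanpop import compute_locus_metrics, individual_call_rates, snp_density

from conftest import make_dataset


def test_worked_example_six_genotypes():
    """codes (0,0,1,1,2,2): hets 1/3, maf 0.5, pic_ref = 1 − (4/9 + 1/9) = 4/9."""
    ds = make_dataset(np.array([[0], [0], [1], [1], [2], [2]]), ["A"] * 6)
    m = compute_locus_metrics(ds).iloc[0]
    assert m["freq_hets"] == pytest.approx(1 / 3)
    assert m["maf"] == pytest.approx(0.5)
    assert m["pic_ref"] == pytest.approx(4 / 9)
    assert m["one_ratio_ref"] == pytest.approx(2 / 3)
    assert m["freq_hom_ref"] + m["freq_hom_snp"] + m["freq_hets"] == pytest.approx(1.0)
    assert m["avg_pic"] == pytest.approx((m["pic_ref"] + m["pic_snp"]) / 2)


def test_monomorphic_and_balanced_extremes():
    ds = make_dataset(np.array([[0, 1], [0, 1]]), ["A", "A"])
    m = compute_locus_metrics(ds)
    assert m.iloc[0]["maf"] == 0 and m.iloc[0]["pic_ref"] == 0 and m.iloc[0]["pic_snp"] == 0
    # all-het locus: one_ratio_ref = one_ratio_snp = 1 → row PIC 0, maf 0.5
    assert m.iloc[1]["maf"] == pytest.approx(0.5)


def test_half_one_ratio_maximizes_pic():
    ds = make_dataset(np.array([[0], [2]]), ["A", "A"])  # one_ratio = 0.5 each row
    m = compute_locus_metrics(ds).iloc[0]
    assert m["pic_ref"] == pytest.approx(0.5)
    assert m["pic_snp"] == pytest.approx(0.5)


def test_uncalled_locus_flagged_nan_not_zero():
    ds = make_dataset(np.array([[-1, 0], [-1, 2]]), ["A", "A"])
    m = compute_locus_metrics(ds)
    assert np.isnan(m.iloc[0]["maf"]) and np.isnan(m.iloc[0]["freq_hets"])
    assert m.iloc[0]["call_rate"] == 0.0


@given(
    st.lists(st.integers(min_value=-1, max_value=2), min_size=2, max_size=40).filter(
        lambda v: any(x != -1 for x in v)
    )
)
def test_maf_invariant_under_allele_relabeling(codes):
    """Swapping ref↔alt (codes 0↔2) leaves maf and avg_pic unchanged."""
    codes = np.asarray(codes)[:, None]
    swapped = np.where(codes == 0, 2, np.where(codes == 2, 0, codes))
    a = compute_locus_metrics(make_dataset(codes, ["A"] * len(codes))).iloc[0]
    b = compute_locus_metrics(make_dataset(swapped, ["A"] * len(codes))).iloc[0]
    assert a["maf"] == pytest.approx(b["maf"])
    assert a["avg_pic"] == pytest.approx(b["avg_pic"])
    assert a["pic_ref"] == pytest.approx(b["pic_snp"])


def test_individual_call_rates():
    codes = np.full((1, 12), 0)
    codes[0, :3] = -1  # 3 missing of 12
    ds = make_dataset(np.vstack([codes, np.full((1, 12), -1), np.zeros((1, 12))]), ["A"] * 3)
    rates = individual_call_rates(ds)
    assert rates.iloc[0] == pytest.approx(0.75)
    assert rates.iloc[1] == 0.0
    assert rates.iloc[2] == 1.0


def test_density_bins_conserve_locus_counts():
    rng = np.random.default_rng(0)
    n = 60
    chroms = rng.integers(1, 4, n)
    positions = rng.integers(1, 1_000_001, n)
    ds = make_dataset(np.zeros((2, n)), ["A", "A"], chromosomes=chroms, positions=positions)
    density = snp_density(ds, bin_bp=200_000)
    for c in np.unique(chroms):
        assert density[str(c)].sum() == (chroms == c).sum()


def test_density_first_bin_half_open():
    ds = make_dataset(np.zeros((1, 2)), ["A"], chromosomes=[1, 1], positions=[1, 200_000])
    d = snp_density(ds, bin_bp=200_000)
    assert d["1"].tolist() == [2]  # pos 200000 still in bin [1, 200000]
    ds2 = make_dataset(np.zeros((1, 1)), ["A"], chromosomes=[1], positions=[200_001])
    assert snp_density(ds2, bin_bp=200_000)["1"].tolist() == [0, 1]
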