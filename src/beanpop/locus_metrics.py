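"""Per-locus marker quality and information indexes.

Implements the DArT report statistics recomputed from genotype codes:
call rate, OneRatioRef/Snp (proportion of called samples in which the
reference / SNP allele row scores present), FreqHomRef/FreqHomSnp/
FreqHets, per-row polymorphism information content (PIC) and their
average, plus minor allele frequency and per-chromosome SNP density.

PIC uses the two-state row convention ``1 − Σ f²`` applied to each
allele row's presence frequency, matching DArT's separate PICRef and
PICSnp columns; for a binary row this is ``2·f·(1−f)`` with maximum 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dart_io import MISSING, SNPDataset

METRIC_COLUMNS = [
    "call_rate", "one_ratio_ref", "one_ratio_snp", "freq_hom_ref",
    "freq_hom_snp", "freq_hets", "pic_ref", "pic_snp", "avg_pic", "maf",
]


def _pic(one_ratio: np.ndarray) -> np.ndarray:
    return 1.0 - (one_ratio**2 + (1.0 - one_ratio) ** 2)


def genotype_counts(ds: SNPDataset) -> pd.DataFrame:
    """Per-locus counts of codes 0/1/2 and called total."""
    g = ds.genotypes
    n0 = (g == 0).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    return pd.DataFrame(
        {"n_hom_ref": n0, "n_het": n1, "n_hom_snp": n2, "n_called": n0 + n1 + n2},
        index=[loc.id for loc in ds.loci],
    )


def compute_locus_metrics(ds: SNPDataset) -> pd.DataFrame:
    """DArT-style indexes per locus, indexed by locus id.

    Fractions are taken over *called* individuals; a locus with zero
    called individuals gets NaN for every frequency-based metric (never
    a silent zero).
    """
    if ds.n_loci == 0 or ds.n_individuals == 0:
        raise ValueError("dataset is empty")
    counts = genotype_counts(ds)
    n = counts["n_called"].to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_n = np.where(n > 0, n, np.nan)
        freq_hom_ref = counts["n_hom_ref"] / safe_n
        freq_hets = counts["n_het"] / safe_n
        freq_hom_snp = counts["n_hom_snp"] / safe_n
        one_ratio_ref = freq_hom_ref + freq_hets
        one_ratio_snp = freq_hom_snp + freq_hets
        p_ref = (2 * counts["n_hom_ref"] + counts["n_het"]) / (2 * safe_n)
        maf = np.minimum(p_ref, 1.0 - p_ref)
    df = pd.DataFrame(
        {
            "call_rate": n / ds.n_individuals,
            "one_ratio_ref": one_ratio_ref,
            "one_ratio_snp": one_ratio_snp,
            "freq_hom_ref": freq_hom_ref,
            "freq_hom_snp": freq_hom_snp,
            "freq_hets": freq_hets,
            "pic_ref": _pic(one_ratio_ref.to_numpy()),
            "pic_snp": _pic(one_ratio_snp.to_numpy()),
            "maf": maf,
        },
        index=counts.index,
    )
    df["avg_pic"] = (df["pic_ref"] + df["pic_snp"]) / 2.0
    return df[METRIC_COLUMNS]


def individual_call_rates(ds: SNPDataset) -> pd.Series:
    """Fraction of non-missing loci per individual, indexed by individual id."""
    called = (ds.genotypes != MISSING).mean(axis=1)
    return pd.Series(called, index=[ind.id for ind in ds.individuals], name="call_rate")


def snp_density(ds: SNPDataset, bin_bp: int = 200_000) -> dict[str, np.ndarray]:
    """Binned counts of mapped loci per chromosome.

    Bins are fixed, non-overlapping and half-open: position ``pos``
    (1-based) falls in bin ``(pos - 1) // bin_bp``.  Counts over all bins
    of a chromosome sum to its mapped locus count.
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    by_chrom: dict[str, list[int]] = {}
    for loc in ds.loci:
        if loc.mapped:
            by_chrom.setdefault(str(loc.chromosome), []).append(loc.position)
    out: dict[str, np.ndarray] = {}
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions)
        n_bins = int((pos.max() - 1) // bin_bp) + 1
        out[chrom] = np.bincount((pos - 1) // bin_bp, minlength=n_bins)
    return out
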