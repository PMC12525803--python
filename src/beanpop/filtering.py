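"""Quality trimming of SNP datasets, with per-stage removal accounting.

The canonical cascade for a DArTseq panel is individuals → loci →
monomorphic: drop low-call-rate individuals first (preserving loci whose
call rate would otherwise be dragged down), then low-call-rate loci,
then loci left monomorphic.  Call-rate thresholds keep values >= the
threshold; the MAF filter keeps strictly > (low-frequency variants are
excluded from LD analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dart_io import MISSING, SNPDataset
from .locus_metrics import compute_locus_metrics, individual_call_rates


@dataclass(frozen=True)
class FilterReport:
    stage: str
    removed: int
    retained: int


def filter_individuals(ds: SNPDataset, min_call: float = 0.8) -> tuple[SNPDataset, FilterReport]:
    """Remove individuals whose call rate is below ``min_call``."""
    keep = individual_call_rates(ds).to_numpy() >= min_call
    if not keep.any():
        raise ValueError(f"filter_individuals: no individual reaches call rate {min_call}")
    report = FilterReport("individual_call_rate", int((~keep).sum()), int(keep.sum()))
    out = ds.subset(individuals=keep)
    out.log(f"filter_individuals(min_call={min_call}): removed {report.removed}, retained {report.retained}")
    return out, report


def filter_loci(ds: SNPDataset, min_call: float = 0.95) -> tuple[SNPDataset, FilterReport]:
    """Remove loci whose call rate is below ``min_call``."""
    call = (ds.genotypes != MISSING).mean(axis=0)
    keep = call >= min_call
    if not keep.any():
        raise ValueError(f"filter_loci: no locus reaches call rate {min_call}")
    report = FilterReport("locus_call_rate", int((~keep).sum()), int(keep.sum()))
    out = ds.subset(loci=keep)
    out.log(f"filter_loci(min_call={min_call}): removed {report.removed}, retained {report.retained}")
    return out, report


def remove_monomorphic(ds: SNPDataset) -> tuple[SNPDataset, FilterReport]:
    """Remove loci whose called genotypes carry a single allele.

    A single heterozygote makes a locus polymorphic (both alleles seen);
    loci with zero called genotypes are treated as monomorphic and
    dropped.
    """
    g = ds.genotypes
    has_ref = ((g == 0) | (g == 1)).any(axis=0)
    has_alt = ((g == 2) | (g == 1)).any(axis=0)
    keep = has_ref & has_alt
    report = FilterReport("monomorphic", int((~keep).sum()), int(keep.sum()))
    out = ds.subset(loci=keep)
    out.log(f"remove_monomorphic: removed {report.removed}, retained {report.retained}")
    return out, report


def filter_maf(ds: SNPDataset, min_maf: float = 0.05) -> tuple[SNPDataset, FilterReport]:
    """Keep loci with minor allele frequency strictly greater than ``min_maf``."""
    maf = compute_locus_metrics(ds)["maf"].to_numpy()
    # strict >, with an epsilon so count-ratio round-off cannot leak a
    # boundary locus (e.g. 1/20 evaluating a hair above 0.05) through
    keep = np.nan_to_num(maf, nan=0.0) > min_maf + 1e-9
    report = FilterReport("maf", int((~keep).sum()), int(keep.sum()))
    out = ds.subset(loci=keep)
    out.log(f"filter_maf(min_maf={min_maf}): removed {report.removed}, retained {report.retained}")
    return out, report
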